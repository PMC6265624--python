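"""Screen every study's control group for Hardy-Weinberg equilibrium.

Controls drawn from the general population should sit near HWE; a small
p-value flags possible genotyping error or selection in that study.
"""

from snpmeta import effect_allele_freq, hwe_test, load_table1

print(f"{'study':22s} {'snp':10s} {'EAF':>6s} {'chi2':>7s} {'p':>6s}")
for rec in load_table1():
    res = hwe_test(rec.control_counts)
    flag = "  <- deviates (p < 0.05)" if res.p_value < 0.05 else ""
    print(f"{rec.study_id:22s} {rec.snp:10s} {res.effect_allele_freq:6.3f} "
          f"{res.chi_square:7.3f} {res.p_value:6.3f}{flag}")

print()
print("EAF is the control effect-allele frequency; the chi-square compares")
print("observed genotype counts with the p^2 / 2pq / q^2 expectation (df=1).")
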