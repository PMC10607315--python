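"""Chi-squared segregation tests on observed mating-type counts.

Three count tables: a 77-strain protoplast test cross (45:32), and two
basidiospore populations typed by three-round mating (97:111:13:25 and
83:40:0:0).  The test asks whether the counts fit the Mendelian 1:1 or
1:1:1:1 expectation; exceeding the upper-0.05 critical value means
segregation distortion.
"""

from matepol import segregation_chi_square

for counts, ratio, label in [
    ((45, 32), (1, 1), "protoplast test cross"),
    ((97, 111, 13, 25), (1, 1, 1, 1), "four-type basidiospore population"),
    ((83, 40, 0, 0), (1, 1, 1, 1), "two-type basidiospore population"),
]:
    res = segregation_chi_square(counts, ratio, alpha=0.05)
    print(f"{label}: {res}")
# chi2=2.195 < 3.84 -> the protoplast ratio is consistent with 1:1, while
# both basidiospore populations (120.24 and 153.07 > 7.81) show strong
# segregation distortion.
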