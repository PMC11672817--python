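"""Pedigree ingestion and relationship-matrix algebra.

Builds a tiny pedigree containing a full-sib mating, computes inbreeding
coefficients, the dense numerator relationship matrix A and its sparse
inverse, and verifies that they are consistent.
"""

import numpy as np

import daysopen as d

# two unrelated founders, two full-sib offspring, one inbred progeny
ped = d.from_triples([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])

F = d.inbreeding(ped)
A = d.build_A(ped)
Ainv = d.build_A_inverse(ped, F=F)

print("animals:", ped.n, "founders:", len(ped.founders))
print("inbreeding F:", np.round(F, 3))
print("A diagonal (1 + F):", np.round(np.diag(A), 3))
print("max |A @ Ainv - I|:", f"{np.abs(A @ Ainv.toarray() - np.eye(ped.n)).max():.2e}")

# F = 0.25 for the progeny of a full-sib mating: its parents share both
# parents, so half of its genome pairs are identical by descent with
# probability 1/2 * 1/2.  The A diagonal is 1 + F, and the sparse inverse
# (Henderson's rules with inbreeding-adjusted Mendelian-sampling variances)
# must invert the tabular A exactly.
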