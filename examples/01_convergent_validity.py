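"""Compare two convergent-validity matrices cell by cell.

Loads the bundled printed intercorrelations of eight loneliness measures
(self-ratings vs aggregated informant-ratings), then asks three
questions: how far apart are corresponding correlations on average (mean
absolute deviation), are the matrices statistically distinguishable (the
chi-square equality test on Fisher-z differences), and how similar are
their overall profiles (double-entry ICC over the 28 unique cells)?
"""

from psyvalid import datasets, matrix_equality_test, matrix_mad
from psyvalid.profiles import matrix_profile_similarity

conv = datasets.load_convergent("study1")
m_self, m_inf = conv["self"], conv["informant"]

mad = matrix_mad(m_self, m_inf)
res = matrix_equality_test(m_self, 679, m_inf, 160, dependent_samples=True)
icc = matrix_profile_similarity(m_self, m_inf)

print(f"mean absolute deviation |dr|: {mad:.3f}")
print(f"equality test: Q = {res.q_statistic:.1f}, df = {res.df}, p = {res.p_value:.2g}")
print(f"profile similarity (z-transformed ICC_DE): {icc:.3f}")
print(f"notes: {res.notes}")

# The MAD says corresponding self- and informant-rated correlations
# differ by ~.09 on average; the large Q rejects equality of the printed
# matrices, driven almost entirely by the direct-frequency single item,
# whose informant-rated correlations are far lower than the self-rated
# ones -- the same column also drags the profile similarity down.
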