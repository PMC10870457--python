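"""Position-specific residue enrichment around crotonylation sites.

Compares residue counts at each window offset between positive and
negative windows with a pseudo-counted log-odds and a binomial test — a
text-table counterpart of a two-class sequence logo.
"""

from kcrnet import GeneratorConfig, generate_peptide_table
from kcrnet.motif import enrichment_from_samples

train_set, test_set = generate_peptide_table(GeneratorConfig(seed=3), 3000, 1000)
table = enrichment_from_samples(train_set + test_set)

print("top 8 enriched/depleted cells (offset relative to the central K):")
for row in table.head(8).itertuples(index=False):
    print(
        f"  {row.residue} at {row.offset:+3d}: log-odds {row.log_odds:+.2f} "
        f"({row.direction}), p = {row.p_value:.2e}"
    )
# With the default generator the D/E enrichment at +/-1, the upstream K
# bias, and the R/P depletion next to the site dominate the ranking --
# the same qualitative pattern reported for real plant Kcr neighborhoods.
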