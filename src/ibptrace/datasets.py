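"""Published worked-example data for the selection-test machinery.

The branch-model log-likelihood pairs reported for the twelve
*D. melanogaster* insulator binding protein genes across insect lineages,
used as input to the likelihood-ratio-test and Bonferroni stages.  Each
row carries the gene, the tested branch, lnL of the neutral (ω ≡ 1) model,
lnL of the branch (foreground-ω) model, and whether the printed row is
arithmetically self-consistent with LRT = 2·(lnL1 − lnL0) (one published
row prints lnL1 < lnL0 together with a positive statistic, an artifact of
the original optimization, and is excluded from exact checks).
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class BranchTestRow:
    gene: str
    branch: str
    lnl0: float
    lnl1: float
    self_consistent: bool = True


IBP_BRANCH_TESTS: list[BranchTestRow] = [
    BranchTestRow("CP190", "Crustacea", -5495.527, -5495.388),
    BranchTestRow("CP190", "Holometabola", -5495.284, -5495.260),
    BranchTestRow("CTCF", "Onychophora", -1314.281, -1310.626),
    BranchTestRow("CTCF", "Holometabola", -1311.997, -1312.166, self_consistent=False),
    BranchTestRow("GAF", "Acerentomon", -2006.810, -2006.810),
    BranchTestRow("GAF", "Holometabola", -2006.810, -2006.810),
    BranchTestRow("Mod(mdg4)", "Polyneoptera", -15377.060, -15377.060),
    BranchTestRow("Mod(mdg4)", "Holometabola", -15374.903, -15373.888),
    BranchTestRow("Pita", "Hymenoptera", -1054.403, -1046.840),
    BranchTestRow("Su(Hw)", "Holometabola", -11052.401, -11052.210),
]

FAMILY_ALPHA = 0.05   # family-wise level over the ten branch tests
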