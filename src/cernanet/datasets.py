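"""Small built-in demonstration fixtures.

These encode published summary-level numbers from the CN-AML ceRNA
literature (the top-ranked lncRNA degree profile and the class-level
differential-expression composition) so that the worked examples and the
ranking arithmetic can be exercised without any external download. Only
summary counts are encoded; the expanded networks/tables built from them
are synthetic and labelled as such.
"""

from __future__ import annotations

import pandas as pd

from .network import CompetingTriplet, build_network

#: (lncRNA, lncRNA-miRNA pairs, miRNA-mRNA pairs) for the ten
#: highest-degree lncRNAs of the CN-AML ceRNA network
CNAML_TOP_LNCRNA_PROFILE = [
    ("XIST", 20, 38),
    ("TUG1", 10, 23),
    ("GABPB1-AS1", 10, 13),
    ("MIRLET7BHG", 7, 11),
    ("AC092127.1", 6, 12),
    ("SNHG1", 6, 9),
    ("NEAT1", 5, 11),
    ("SNHG3", 5, 9),
    ("H19", 5, 9),
    ("AC074117.1", 5, 9),
]

#: class-level DE composition of the CN-AML cohorts: rna_class -> (n_total, n_up)
CNAML_DE_COMPOSITION = {
    "mRNA": (127, 76),
    "lncRNA": (3380, 1751),
    "miRNA": (82, 19),
}


def profile_triplets(profile=None):
    """Expand a per-lncRNA (first, secondary) pair profile into triplets.

    Each lncRNA gets its own synthetic miRNA partners (one per first-
    relationship pair) and each miRNA-mRNA pair gets a fresh synthetic
    mRNA, distributed round-robin over the miRNAs — so the resulting
    network reproduces the profile's degree and pair counts exactly.
    All triplets are placed in the lncRNA-upregulated group.
    """
    profile = CNAML_TOP_LNCRNA_PROFILE if profile is None else profile
    triplets = []
    for lnc, first, secondary in profile:
        if secondary < first:
            raise ValueError(
                f"{lnc}: secondary pairs ({secondary}) < first pairs ({first}); "
                "every miRNA partner needs at least one mRNA edge under this expansion"
            )
        mirnas = [f"mir:{lnc}:{j}" for j in range(first)]
        for e in range(secondary):
            mirna = mirnas[e % first]
            mrna = f"mrna:{lnc}:{e}"
            triplets.append(CompetingTriplet(lnc, mirna, mrna, "lnc_up"))
    return sorted(triplets)


def profile_network(profile=None):
    """The lnc_up network realising a (first, secondary) profile."""
    up, _down = build_network(profile_triplets(profile))
    return up


def composition_de_table(composition=None) -> pd.DataFrame:
    """A synthetic screened DE table realising per-class (n_total, n_up) counts.

    Gene ids, fold changes and p-values are placeholders; only the class
    membership and direction counts are meaningful.
    """
    composition = CNAML_DE_COMPOSITION if composition is None else composition
    rows = []
    for cls, (n_total, n_up) in composition.items():
        for i in range(n_total):
            up = i < n_up
            rows.append({
                "gene": f"{cls}:{i:05d}",
                "rna_class": cls,
                "log2fc": 2.0 if up else -2.0,
                "pvalue": 0.001,
                "adj_pvalue": 0.01,
                "direction": "up" if up else "down",
            })
    return pd.DataFrame(rows)
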