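"""Bundled reference dataset: the TK001 *E. coli* phage panel.

A published characterization of 13 coliphages isolated on the murine
*E. coli* strain TK001 (ΦWec172-ΦWec196), later extended with ΦWec270,
ΦWec272 and the FhuA-targeting reference phage T5. The dataset carries:

* the 13 phage-resistant TK001 mutant strains with their frameshift /
  stop-codon mutated genes and pathway roles (LPS biosynthesis vs
  membrane-protein/flagellar genes);
* the per-phage reduction calls against those strains (strict
  log10 EoP < -1 rule);
* the published binary receptor-requirement matrix (which host genes each
  phage needs to infect, lettered into receptor types a-g);
* the override table that resolves multi-gene-mutant ambiguities using the
  complementation and Keio single-knockout evidence reported alongside the
  screen;
* the physiological clusters P1-P5 obtained from Gower-distance
  complete-linkage clustering of the phages' phenotypes.

These tables are desk-scale inputs for worked examples and cross-checks;
``phagepanel.simulate`` generates arbitrarily parameterized lookalikes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eop import ReceptorProfile, assign_receptor_types
from .io import MutantGeneMap, Partition

__all__ = [
    "PHAGES_13",
    "PHAGES_16",
    "LPS_GENES",
    "mutant_gene_map",
    "gene_roles",
    "reduction_table",
    "table_overrides",
    "receptor_profile",
    "receptor_partition",
    "physiological_partition",
]

PHAGES_13 = [
    "PhiWec172", "PhiWec174", "PhiWec177", "PhiWec179", "PhiWec181",
    "PhiWec186", "PhiWec187", "PhiWec188", "PhiWec190", "PhiWec189",
    "PhiWec191", "PhiWec193", "PhiWec196",
]
#: 13 originals plus the validation phages (same receptor family as the
#: PhiWec189 group for 270/272; T5 targets FhuA, untouched by the mutants).
PHAGES_16 = PHAGES_13 + ["PhiWec270", "PhiWec272", "T5"]

#: LPS-biosynthesis genes among the mutated genes (waa core-synthesis genes
#: plus the O-antigen sugar genes wecA and manB-1).
LPS_GENES = frozenset({"waaV", "waaW", "waaT", "waaY", "waaG", "wecA", "manB-1"})

# resistant strain -> mutated genes (frameshift or stop codon)
_MUTANT_GENES: dict[str, tuple[str, ...]] = {
    "R172": ("waaV",),
    "R174": ("waaW",),
    "R177-1": ("waaV",),
    "R177-2": ("waaV", "wecA"),
    "R181": ("manB-1", "waaT"),
    "R186": ("flhD", "bcsG"),
    "R187": ("bcsG",),
    "R188": ("yhaH",),
    "R189": ("nfrB", "ompA"),
    "R190": ("waaG",),
    "R191": ("nfrB", "tolA"),
    "R193": ("waaY",),
    "R196": ("waaY",),
}

_GENE_ROLES: dict[str, str] = {
    "waaV": "LPS beta-1,3-glucosyltransferase",
    "waaW": "LPS alpha-1,2-galactosyltransferase",
    "waaT": "LPS 1,2-glucosyltransferase",
    "waaY": "LPS core heptose(II) kinase",
    "waaG": "LPS alpha-1,3-glucosyltransferase",
    "wecA": "O-antigen sugar transferase (Und-P GlcNAc-1-P transferase)",
    "manB-1": "mannose-1-phosphate guanylyltransferase (O-antigen sugar)",
    "flhD": "flagellar transcriptional regulator",
    "bcsG": "cellulose biosynthesis protein",
    "yhaH": "inner membrane protein",
    "nfrB": "phage N4 adsorption protein B",
    "ompA": "outer membrane protein A",
    "tolA": "TolA membrane-spanning protein",
}

# which phages each resistant strain blocks (EoP reduced > 10-fold);
# T5 is blocked by none, and R187 blocks nothing.
_BLOCKS: dict[str, tuple[str, ...]] = {
    "R172": ("PhiWec172", "PhiWec174", "PhiWec177"),
    "R174": ("PhiWec172", "PhiWec174", "PhiWec177"),
    "R177-1": ("PhiWec172", "PhiWec174", "PhiWec177"),
    "R177-2": ("PhiWec172", "PhiWec174", "PhiWec177"),
    "R181": ("PhiWec179", "PhiWec181", "PhiWec186", "PhiWec188", "PhiWec190"),
    "R186": ("PhiWec179", "PhiWec181", "PhiWec186"),
    "R187": (),
    "R188": ("PhiWec188", "PhiWec190"),
    "R189": ("PhiWec189", "PhiWec191", "PhiWec193", "PhiWec196",
             "PhiWec270", "PhiWec272"),
    "R190": tuple(p for p in PHAGES_16 if p != "T5"),
    "R191": ("PhiWec189", "PhiWec191", "PhiWec193", "PhiWec196",
             "PhiWec270", "PhiWec272"),
    "R193": ("PhiWec174", "PhiWec177", "PhiWec187", "PhiWec189", "PhiWec191",
             "PhiWec193", "PhiWec196", "PhiWec270", "PhiWec272"),
    "R196": ("PhiWec174", "PhiWec177", "PhiWec187", "PhiWec189", "PhiWec191",
             "PhiWec193", "PhiWec196", "PhiWec270", "PhiWec272"),
}

# published receptor-requirement matrix (gene columns in published order)
_PROFILE_GENES = ["waaV", "waaW", "waaY", "waaT", "flhD", "yhaH", "nfrB", "tolA"]
_PROFILE_ROWS: dict[str, tuple[int, ...]] = {
    "PhiWec172": (1, 1, 0, 0, 0, 0, 0, 0),
    "PhiWec174": (1, 1, 1, 0, 0, 0, 0, 0),
    "PhiWec177": (1, 1, 1, 0, 0, 0, 0, 0),
    "PhiWec179": (0, 0, 0, 1, 1, 0, 0, 0),
    "PhiWec181": (0, 0, 0, 1, 1, 0, 0, 0),
    "PhiWec186": (0, 0, 0, 1, 1, 0, 0, 0),
    "PhiWec187": (0, 0, 1, 0, 0, 0, 0, 0),
    "PhiWec188": (0, 0, 0, 1, 0, 1, 0, 0),
    "PhiWec190": (0, 0, 0, 1, 0, 1, 0, 0),
    "PhiWec189": (0, 0, 1, 0, 0, 0, 1, 1),
    "PhiWec191": (0, 0, 1, 0, 0, 0, 1, 1),
    "PhiWec193": (0, 0, 1, 0, 0, 0, 1, 1),
    "PhiWec196": (0, 0, 1, 0, 0, 0, 1, 1),
    "PhiWec270": (0, 0, 1, 0, 0, 0, 1, 1),
    "PhiWec272": (0, 0, 1, 0, 0, 0, 1, 1),
    "T5": (0, 0, 0, 0, 0, 0, 0, 0),
}

# physiological clusters from Gower + complete-linkage clustering
_PHYSIO_13: dict[str, str] = {
    "PhiWec189": "P1", "PhiWec191": "P1", "PhiWec193": "P1", "PhiWec196": "P1",
    "PhiWec172": "P2", "PhiWec174": "P2", "PhiWec177": "P2",
    "PhiWec179": "P3", "PhiWec181": "P3", "PhiWec186": "P3",
    "PhiWec187": "P4", "PhiWec188": "P4", "PhiWec190": "P4",
}
_PHYSIO_EXTRA: dict[str, str] = {"PhiWec270": "P1", "PhiWec272": "P1", "T5": "P5"}


def mutant_gene_map() -> MutantGeneMap:
    """The 13 resistant TK001 strains and their mutated genes."""
    return MutantGeneMap({s: list(gs) for s, gs in _MUTANT_GENES.items()})


def gene_roles() -> dict[str, str]:
    """Pathway/function annotation for each mutated gene."""
    return dict(_GENE_ROLES)


def reduction_table(n_phages: int = 13) -> pd.DataFrame:
    """Boolean phage x strain reduction calls against the mutant panel."""
    phages = _phage_set(n_phages)
    strains = list(_MUTANT_GENES)
    return pd.DataFrame(
        [[p in _BLOCKS[s] for s in strains] for p in phages],
        index=phages, columns=strains, dtype=bool,
    )


def table_overrides(n_phages: int = 13) -> dict[tuple[str, str], int]:
    """Overrides resolving multi-gene-mutant ambiguity, per the published evidence.

    waaG is required by every phage except T5 (the whole panel loses the
    strain), so it is non-discriminative and zeroed in the published matrix;
    complementation and Keio-knockout results attribute the R181 double
    mutant to waaT (not manB-1), the R177-2 double to waaV (not wecA), and
    the R189/R191 doubles to nfrB plus tolA (not ompA).
    """
    phages = _phage_set(n_phages)
    ov: dict[tuple[str, str], int] = {}
    for p in phages:
        if p != "T5":
            ov[(p, "waaG")] = 0
    for p in ("PhiWec172", "PhiWec174", "PhiWec177"):
        if p in phages:
            ov[(p, "wecA")] = 0
    for p in ("PhiWec179", "PhiWec181", "PhiWec186", "PhiWec188", "PhiWec190"):
        if p in phages:
            ov[(p, "manB-1")] = 0
            ov[(p, "waaT")] = 1
    for p in ("PhiWec189", "PhiWec191", "PhiWec193", "PhiWec196",
              "PhiWec270", "PhiWec272"):
        if p in phages:
            ov[(p, "ompA")] = 0
            ov[(p, "nfrB")] = 1
            ov[(p, "tolA")] = 1
    return ov


def _phage_set(n_phages: int) -> list[str]:
    if n_phages == 13:
        return list(PHAGES_13)
    if n_phages == 16:
        return list(PHAGES_16)
    raise ValueError("the bundled dataset covers 13 or 16 phages")


def receptor_profile(n_phages: int = 13) -> ReceptorProfile:
    """The published binary receptor-requirement matrix."""
    phages = _phage_set(n_phages)
    values = np.array([_PROFILE_ROWS[p] for p in phages], dtype=np.int8)
    return ReceptorProfile(phages, list(_PROFILE_GENES), values)


def receptor_partition(n_phages: int = 13) -> Partition:
    """Receptor types (a-g) computed from the requirement matrix."""
    return assign_receptor_types(receptor_profile(n_phages)).as_partition()


def physiological_partition(n_phages: int = 13) -> Partition:
    """Physiological clusters P1-P4 (13 phages) or P1-P5 (16 phages)."""
    phages = _phage_set(n_phages)
    members = {**_PHYSIO_13, **_PHYSIO_EXTRA}
    return Partition(phages, [members[p] for p in phages])
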