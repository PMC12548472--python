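"""Efficiency-of-plating analysis and receptor-requirement typing.

Spot-test titers are converted to EoP values relative to a wild-type
reference strain; a strict greater-than-10-fold drop (log10 EoP < -1) is
called a reduction in infection efficiency. Reduction calls against a panel
of resistant mutant strains, each annotated with its knocked-out genes,
are then turned into a binary receptor-requirement profile per phage
(which host genes the phage needs to infect), and phages with identical
profiles are grouped into lettered receptor types.

Attribution from multi-gene mutants follows a subset-exoneration rule: a
gene is cleared of involvement only when an observed strain whose mutated
genes are a subset of a blocking strain's genes fails to block the phage
(e.g. a single-gene mutant that the phage still infects). Requirements
that rest solely on inseparable multi-gene knockouts are kept but flagged
ambiguous; an explicit override table (typically complementation or
knockout-library evidence) resolves them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NEG_INF, EoPRecord, MutantGeneMap, TiterObservation

__all__ = [
    "compute_eop",
    "aggregate_replicates",
    "call_reduction",
    "adsorption_rate",
    "eop_table",
    "reduction_frame",
    "ReceptorProfile",
    "ReceptorTyping",
    "derive_receptor_profile",
    "assign_receptor_types",
    "strains_with_any_gene",
]

REDUCTION_LOG_EOP = -1.0  # strict: log10 EoP < -1 is a reduction
ADSORPTION_THRESHOLD = 20.0  # strict: rate < 20% marks a receptor mutant


def compute_eop(titer_test: float | None, titer_reference: float) -> tuple[float, float]:
    """Return ``(eop, log_eop)`` for one test titer against the reference titer.

    ND (``None``) or zero test titers mean complete loss of infectivity:
    EoP 0 with the ``NEG_INF`` log sentinel.
    """
    if titer_reference is None or not math.isfinite(titer_reference) or titer_reference <= 0:
        raise ValueError("reference titer must be a finite positive count (ND not allowed)")
    if titer_test is None or titer_test == 0:
        return 0.0, NEG_INF
    if titer_test < 0 or not math.isfinite(titer_test):
        raise ValueError(f"test titer must be ND or finite nonnegative, got {titer_test!r}")
    eop = titer_test / titer_reference
    return eop, math.log10(eop)


def aggregate_replicates(log_eops: Sequence[float]) -> tuple[float, int]:
    """Average finite replicate log-EoP values, discarding ND sentinels.

    Returns ``(summary, n_used)``. An all-ND replicate set stays ND
    (``NEG_INF``, 0 used).
    """
    if len(log_eops) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    finite = [x for x in log_eops if x != NEG_INF]
    for x in finite:
        if not math.isfinite(x):
            raise ValueError(f"log_eop values must be finite or NEG_INF, got {x!r}")
    if not finite:
        return NEG_INF, 0
    return float(np.mean(finite)), len(finite)


def call_reduction(log_eop: float) -> bool:
    """Strict reduction call: more than a 10-fold EoP drop (log10 EoP < -1)."""
    return log_eop < REDUCTION_LOG_EOP


def adsorption_rate(plaques_t0: float, plaques_t10: float) -> tuple[float, bool]:
    """Adsorption rate (%) from free-phage plaque counts at 0 and 10 minutes.

    ``rate = 100 * (1 - plaques_t10 / plaques_t0)``; strains adsorbing less
    than 20% of phage are called target-receptor mutants (strict).
    """
    if plaques_t0 is None or plaques_t0 <= 0:
        raise ValueError("plaque count at t=0 must be positive")
    if plaques_t10 < 0:
        raise ValueError("plaque count at t=10 must be nonnegative")
    rate = 100.0 * (plaques_t0 - plaques_t10) / plaques_t0
    return rate, rate < ADSORPTION_THRESHOLD


def eop_table(titers: Iterable[TiterObservation], reference_strain: str) -> list[EoPRecord]:
    """Convert spot-test titers into replicate-aggregated EoP records.

    The reference titer per phage is the mean of its (finite, positive)
    wild-type replicates; each test replicate's log EoP is computed against
    it and replicates are averaged with ND values discarded.
    """
    by_phage: dict[str, dict[str, list[TiterObservation]]] = {}
    for obs in titers:
        by_phage.setdefault(obs.phage_id, {}).setdefault(obs.strain_id, []).append(obs)

    records: list[EoPRecord] = []
    for phage, by_strain in by_phage.items():
        refs = by_strain.get(reference_strain)
        if not refs:
            raise ValueError(f"phage {phage!r} has no titers on reference strain "
                             f"{reference_strain!r}")
        if any(o.is_nd or o.titer <= 0 for o in refs):
            raise ValueError(f"phage {phage!r}: reference strain titers must be "
                             "positive and countable (not ND)")
        ref_titer = float(np.mean([o.titer for o in refs]))
        for strain, obs_list in by_strain.items():
            if strain == reference_strain:
                continue
            log_eops = [compute_eop(o.titer, ref_titer)[1] for o in obs_list]
            summary, n_used = aggregate_replicates(log_eops)
            eop = 0.0 if summary == NEG_INF else 10.0 ** summary
            records.append(
                EoPRecord(phage, strain, eop, summary, call_reduction(summary), n_used)
            )
    return records


def reduction_frame(records: Iterable[EoPRecord]) -> pd.DataFrame:
    """Pivot EoP records into a phage x strain boolean reduction table."""
    rows: dict[str, dict[str, bool]] = {}
    for r in records:
        rows.setdefault(r.phage_id, {})[r.strain_id] = r.reduced
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.isna().any().any():
        missing = [(p, s) for p in df.index for s in df.columns if pd.isna(df.at[p, s])]
        raise ValueError(f"reduction table has uncovered phage-strain pairs: {missing[:5]}")
    return df.astype(bool)


# ---------------------------------------------------------------------------
# receptor profiles and types
# ---------------------------------------------------------------------------


@dataclass
class ReceptorProfile:
    """Binary phage x gene requirement matrix (1 = gene needed for infection).

    ``ambiguous`` flags entries whose attribution rests only on multi-gene
    mutants that no subset relation could separate.
    """

    phage_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    ambiguous: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        shape = (len(self.phage_ids), len(self.gene_ids))
        if self.values.shape != shape:
            raise ValueError(f"profile shape {self.values.shape} != {shape}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")
        if self.ambiguous is None:
            self.ambiguous = np.zeros(shape, dtype=bool)
        self.ambiguous = np.asarray(self.ambiguous, dtype=bool)
        if self.ambiguous.shape != shape:
            raise ValueError("ambiguity flag shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.phage_ids, columns=self.gene_ids)

    def row(self, phage: str) -> dict[str, int]:
        i = self.phage_ids.index(phage)
        return dict(zip(self.gene_ids, self.values[i].tolist()))

    def restrict_genes(self, genes: Sequence[str]) -> "ReceptorProfile":
        idx = [self.gene_ids.index(g) for g in genes]
        return ReceptorProfile(list(self.phage_ids), list(genes),
                               self.values[:, idx], self.ambiguous[:, idx])

    def drop_empty_genes(self) -> "ReceptorProfile":
        keep = [g for j, g in enumerate(self.gene_ids) if self.values[:, j].any()]
        return self.restrict_genes(keep)


@dataclass
class ReceptorTyping:
    """Phage -> lettered receptor type, letters in order of first appearance."""

    labels: dict[str, str]
    representatives: dict[str, dict[str, int]]

    @property
    def n_types(self) -> int:
        return len(self.representatives)

    def as_partition(self):
        from .io import Partition

        return Partition(list(self.labels.keys()), list(self.labels.values()))


def _type_letters():
    """a, b, ..., z, aa, ab, ... — spreadsheet-style letter sequence."""
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def derive_receptor_profile(
    reduction: pd.DataFrame,
    genes: MutantGeneMap,
    overrides: Mapping[tuple[str, str], int] | None = None,
) -> ReceptorProfile:
    """Infer which host genes each phage requires from mutant reduction calls.

    Parameters
    ----------
    reduction
        Boolean phage x strain table; True where the strain blocks the phage
        (EoP reduced more than 10-fold).
    genes
        Mutated genes of each strain in ``reduction``.
    overrides
        Optional ``(phage, gene) -> 0/1`` corrections from external evidence
        (complementation, single-knockout libraries); applied last, clearing
        ambiguity flags.

    For each phage the candidate genes are the union of gene sets of its
    blocking strains. A candidate g is exonerated when a strain that does
    not block the phage carries a gene set containing g that is a subset of
    some blocking strain's set (the single-mutant case is the subset {g}).
    Surviving candidates are required; a requirement is flagged ambiguous
    unless some blocking strain's surviving genes reduce to exactly that
    gene.
    """
    strains = list(reduction.columns)
    missing = [s for s in strains if s not in genes]
    if missing:
        raise ValueError(f"strains missing from mutant gene map: {missing}")

    gene_order = [g for g in genes.all_genes()
                  if any(g in genes[s] for s in strains)]
    if overrides:
        for (_, g) in overrides:
            if g not in gene_order:
                gene_order.append(g)
    gene_idx = {g: j for j, g in enumerate(gene_order)}

    phages = list(reduction.index)
    values = np.zeros((len(phages), len(gene_order)), dtype=np.int8)
    flags = np.zeros_like(values, dtype=bool)

    for i, phage in enumerate(phages):
        blocking = [s for s in strains if bool(reduction.at[phage, s])]
        nonblocking = [s for s in strains if not bool(reduction.at[phage, s])]
        candidates: set[str] = set()
        for s in blocking:
            candidates |= genes[s]
        exonerated: set[str] = set()
        for s_nb in nonblocking:
            if any(genes[s_nb] <= genes[s_b] for s_b in blocking):
                exonerated |= genes[s_nb]
        surviving = candidates - exonerated
        for g in surviving:
            values[i, gene_idx[g]] = 1
            separated = any(
                g in genes[s_b] and (genes[s_b] & surviving) == {g} for s_b in blocking
            )
            flags[i, gene_idx[g]] = not separated

    if overrides:
        phage_idx = {p: i for i, p in enumerate(phages)}
        for (p, g), v in overrides.items():
            if p not in phage_idx:
                raise ValueError(f"override for unknown phage {p!r}")
            if v not in (0, 1):
                raise ValueError(f"override value for ({p!r}, {g!r}) must be 0/1")
            values[phage_idx[p], gene_idx[g]] = v
            flags[phage_idx[p], gene_idx[g]] = False

    return ReceptorProfile(phages, gene_order, values, flags)


def assign_receptor_types(
    profile: ReceptorProfile, phage_subset: Sequence[str] | None = None
) -> ReceptorTyping:
    """Group phages with identical requirement rows into lettered types.

    Ambiguity flags are ignored; letters a, b, c, ... are assigned in order
    of first appearance along the (subset of the) phage ordering.
    """
    if phage_subset is None:
        phage_subset = profile.phage_ids
    else:
        unknown = [p for p in phage_subset if p not in profile.phage_ids]
        if unknown:
            raise ValueError(f"unknown phage ids: {unknown}")
    letters = _type_letters()
    labels: dict[str, str] = {}
    reps: dict[str, dict[str, int]] = {}
    seen: dict[tuple[int, ...], str] = {}
    for p in phage_subset:
        row = tuple(profile.values[profile.phage_ids.index(p)].tolist())
        if row not in seen:
            letter = next(letters)
            seen[row] = letter
            reps[letter] = dict(zip(profile.gene_ids, row))
        labels[p] = seen[row]
    return ReceptorTyping(labels, reps)


def strains_with_any_gene(genes: MutantGeneMap, gene_set: Iterable[str]) -> list[str]:
    """Strains carrying a mutation in at least one of the given genes.

    The canonical use is counting strains hit in a pathway, e.g. LPS
    biosynthesis (waa/wec/manB genes).
    """
    gs = set(gene_set)
    return [s for s in genes.strain_ids if genes[s] & gs]
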