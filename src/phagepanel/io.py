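"""Shared data types and readers/writers for the phage phenotyping pipeline.

The pipeline moves through a fixed chain of containers: spot-test titers
(:class:`TiterObservation`) become efficiency-of-plating records
(:class:`EoPRecord`), which — combined with a :class:`MutantGeneMap` of
resistant-strain knockouts — yield a binary receptor-requirement profile.
Host-range screens live in an :class:`InfectionMatrix`; mixed binary +
quantitative assay features live in a :class:`PhenotypeTable`; clustering
passes through :class:`DistanceMatrix`, :class:`Dendrogram`,
:class:`Partition` and :class:`SilhouetteSweep`; partition comparisons end in
a :class:`ConcordanceResult`.

Conventions
-----------
* All tables are phage-rows x strain/feature-columns.
* Row/column order is preserved end-to-end: type letters and greedy
  tie-breaking depend on input order.
* "ND" (not detected, case-insensitive) in titer files marks a spot test
  with no plaques at any dilution; internally ND titers are ``None`` and
  the corresponding log-EoP is the ``NEG_INF`` sentinel.
* Missing phenotype cells are the empty string or "NA" on disk and NaN in
  memory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

NEG_INF = float("-inf")

__all__ = [
    "NEG_INF",
    "TiterObservation",
    "EoPRecord",
    "MutantGeneMap",
    "InfectionMatrix",
    "FeatureSpec",
    "PhenotypeTable",
    "DistanceMatrix",
    "Dendrogram",
    "Partition",
    "SilhouetteSweep",
    "ConcordanceResult",
    "read_infection_matrix",
    "write_infection_matrix",
    "read_titers",
    "write_titers",
    "read_mutant_genes",
    "write_mutant_genes",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_partition",
    "write_partition",
    "read_newick",
]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
        return "," if dialect == "csv" else "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# spot-test records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TiterObservation:
    """One phage-strain spot-test measurement.

    ``titer`` is a PFU-equivalent count; ``None`` encodes ND (no plaques
    detected at any dilution).
    """

    phage_id: str
    strain_id: str
    titer: float | None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.titer is not None:
            if not math.isfinite(self.titer) or self.titer < 0:
                raise ValueError(
                    f"titer must be ND or a finite nonnegative number, got {self.titer!r}"
                )
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")

    @property
    def is_nd(self) -> bool:
        return self.titer is None


@dataclass(frozen=True)
class EoPRecord:
    """Efficiency of plating of one phage on one strain, relative to wild type.

    ``eop == 0`` iff ``log_eop`` is the ``NEG_INF`` sentinel; ``reduced`` is
    the strict ``log_eop < -1`` call (a greater-than-10-fold drop).
    """

    phage_id: str
    strain_id: str
    eop: float
    log_eop: float
    reduced: bool
    n_replicates_used: int = 1

    def __post_init__(self) -> None:
        if self.eop < 0:
            raise ValueError("eop must be nonnegative")
        if (self.eop == 0) != (self.log_eop == NEG_INF):
            raise ValueError("eop == 0 must coincide with log_eop == NEG_INF")
        if self.reduced != (self.log_eop < -1.0):
            raise ValueError("reduced flag inconsistent with log_eop < -1 rule")


class MutantGeneMap:
    """Mapping from resistant-strain id to the set of genes mutated in it."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {}
        self._order: list[str] = []
        for strain, genes in mapping.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"strain {strain!r} maps to no genes")
            if any((not g) or (not isinstance(g, str)) for g in gs):
                raise ValueError(f"strain {strain!r} has an empty/non-string gene id")
            if strain in self._map:
                raise ValueError(f"duplicate strain id: {strain!r}")
            self._map[strain] = gs
            self._order.append(strain)

    def __getitem__(self, strain: str) -> frozenset[str]:
        return self._map[strain]

    def __contains__(self, strain: str) -> bool:
        return strain in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._order)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutantGeneMap) and self._map == other._map

    @property
    def strain_ids(self) -> list[str]:
        return list(self._order)

    def genes(self, strain: str) -> frozenset[str]:
        return self._map[strain]

    def all_genes(self) -> list[str]:
        """All gene ids, ordered by first appearance (alphabetical within a strain)."""
        out: list[str] = []
        seen: set[str] = set()
        for strain in self._order:
            for g in sorted(self._map[strain]):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------


@dataclass
class InfectionMatrix:
    """Binary phage x strain infectivity table (1 = infects)."""

    phage_ids: list[str]
    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.phage_ids), len(self.strain_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.phage_ids)} phages x {len(self.strain_ids)} strains"
            )
        _check_unique(self.phage_ids, "phage")
        _check_unique(self.strain_ids, "strain")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at phage {self.phage_ids[bad[0]]!r}, "
                f"strain {self.strain_ids[bad[1]]!r}: {self.values[tuple(bad)]!r}"
            )
        self.values = self.values.astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.phage_ids, columns=self.strain_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InfectionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InfectionMatrix)
            and self.phage_ids == other.phage_ids
            and self.strain_ids == other.strain_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one phenotype column: binary or quantitative, with weight."""

    name: str
    kind: str  # "binary" | "quantitative"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"feature kind must be binary/quantitative, got {self.kind!r}")
        if self.weight < 0:
            raise ValueError("feature weight must be >= 0")


@dataclass
class PhenotypeTable:
    """Mixed binary + quantitative phage features, NaN marking missing cells."""

    phage_ids: list[str]
    features: list[FeatureSpec]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.phage_ids, "phage")
        _check_unique([f.name for f in self.features], "feature")
        self.values = self.values.astype(float)
        if list(self.values.index) != list(self.phage_ids):
            self.values = self.values.loc[self.phage_ids]
        if list(self.values.columns) != [f.name for f in self.features]:
            self.values = self.values[[f.name for f in self.features]]
        for f in self.features:
            col = self.values[f.name]
            obs = col.dropna()
            if f.kind == "binary" and not obs.isin((0.0, 1.0)).all():
                raise ValueError(f"binary feature {f.name!r} has values outside {{0,1}}")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    item_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        _check_unique(self.item_ids, "item")
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)

    def __len__(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)


@dataclass
class Dendrogram:
    """Agglomeration record: leaves 0..n-1, merge i creates node n+i.

    ``merges`` holds (left_node, right_node, height, size) in merge order;
    heights are nondecreasing for complete linkage.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        prev = -math.inf
        for left, right, height, size in self.merges:
            if height < prev - 1e-12:
                raise ValueError("merge heights must be nondecreasing")
            prev = max(prev, height)
            if size < 2:
                raise ValueError("merged cluster size must be >= 2")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class Partition:
    """A labelling of items into groups; labels are opaque strings."""

    item_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.item_ids, "item")
        if len(self.item_ids) != len(self.labels):
            raise ValueError("one label per item required")
        if self.item_ids and not self.labels:
            raise ValueError("partition needs at least one label")

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "Partition":
        return cls(list(d.keys()), [str(v) for v in d.values()])

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.item_ids, self.labels))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item, lab in zip(self.item_ids, self.labels):
            out.setdefault(lab, []).append(item)
        return out

    def restrict(self, items: Sequence[str]) -> "Partition":
        d = self.as_dict()
        missing = [x for x in items if x not in d]
        if missing:
            raise KeyError(f"items not in partition: {missing}")
        return Partition(list(items), [d[x] for x in items])

    @property
    def n_groups(self) -> int:
        return len(set(self.labels))


@dataclass
class SilhouetteSweep:
    """Average silhouette width per candidate k and the selected k."""

    ks: list[int]
    scores: list[float]
    chosen_k: int

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.scores) or not self.ks:
            raise ValueError("one score per k required")
        best = max(self.scores)
        winners = [k for k, s in zip(self.ks, self.scores) if s == best]
        if self.chosen_k != min(winners):
            raise ValueError("chosen_k must be the smallest k attaining the maximum score")


@dataclass(frozen=True)
class ConcordanceEntry:
    name_a: str
    name_b: str
    ari: float
    ari_rounded: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.ari <= 1.0 + 1e-12):
            raise ValueError("ARI must lie in [-1, 1]")


@dataclass
class ConcordanceResult:
    """Pairwise ARI table across named partitions."""

    entries: list[ConcordanceEntry] = field(default_factory=list)

    def get(self, a: str, b: str) -> float:
        for e in self.entries:
            if {e.name_a, e.name_b} == {a, b}:
                return e.ari
        raise KeyError(f"no comparison for pair ({a!r}, {b!r})")

    def to_records(self) -> list[dict]:
        return [
            {"pair": [e.name_a, e.name_b], "ari": e.ari, "ari_rounded": e.ari_rounded}
            for e in self.entries
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_infection_matrix(path: str | Path, dialect: str | None = None) -> InfectionMatrix:
    """Read a binary phage x strain matrix (first row strain ids, first column phage ids)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=np.int8)
    for i, phage in enumerate(df.index):
        for j, strain in enumerate(df.columns):
            cell = str(df.iat[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at phage {phage!r}, strain {strain!r}"
                )
            values[i, j] = int(cell)
    return InfectionMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)


def write_infection_matrix(matrix: InfectionMatrix, path: str | Path,
                           dialect: str | None = None) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path, dialect), index_label="phage")


def read_titers(path: str | Path, dialect: str | None = None) -> list[TiterObservation]:
    """Read long-format titers: columns phage, strain, replicate, titer (ND allowed)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    required = {"phage", "strain", "replicate", "titer"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: titer table needs columns {sorted(required)}")
    out: list[TiterObservation] = []
    seen: set[tuple[str, str, int]] = set()
    for _, row in df.iterrows():
        raw = str(row["titer"]).strip()
        titer = None if raw.lower() == "nd" else float(raw)
        rep = int(row["replicate"])
        key = (row["phage"], row["strain"], rep)
        if key in seen:
            raise ValueError(f"{path}: duplicate observation {key}")
        seen.add(key)
        out.append(TiterObservation(str(row["phage"]), str(row["strain"]), titer, rep))
    return out


def write_titers(obs: Sequence[TiterObservation], path: str | Path,
                 dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "phage": [o.phage_id for o in obs],
            "strain": [o.strain_id for o in obs],
            "replicate": [o.replicate for o in obs],
            "titer": ["ND" if o.is_nd else repr(o.titer) for o in obs],
        }
    )
    df.to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_mutant_genes(path: str | Path, dialect: str | None = None) -> MutantGeneMap:
    """Read a long-format strain/gene table (one mutated gene per row)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    if not {"strain", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: mutant table needs columns ['strain', 'gene']")
    mapping: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(str(row["strain"]), []).append(str(row["gene"]))
    return MutantGeneMap(mapping)


def write_mutant_genes(genes: MutantGeneMap, path: str | Path,
                       dialect: str | None = None) -> None:
    path = Path(path)
    rows = [(s, g) for s in genes.strain_ids for g in sorted(genes[s])]
    pd.DataFrame(rows, columns=["strain", "gene"]).to_csv(
        path, sep=_sep_for(path, dialect), index=False
    )


def read_phenotype_table(path: str | Path, dialect: str | None = None,
                         kinds: Mapping[str, str] | None = None,
                         weights: Mapping[str, float] | None = None) -> PhenotypeTable:
    """Read a phage x feature table; "" or "NA" cells are missing.

    Column kinds are inferred (binary iff every observed value is 0/1) unless
    overridden through ``kinds``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0,
                     na_values=["NA", ""], keep_default_na=False)
    df = df.astype(float)
    feats = []
    for name in df.columns:
        obs = df[name].dropna()
        if kinds and name in kinds:
            kind = kinds[name]
        else:
            kind = "binary" if len(obs) and obs.isin((0.0, 1.0)).all() else "quantitative"
        w = weights.get(name, 1.0) if weights else 1.0
        feats.append(FeatureSpec(str(name), kind, w))
    return PhenotypeTable(list(map(str, df.index)), feats, df)


def write_phenotype_table(table: PhenotypeTable, path: str | Path,
                          dialect: str | None = None) -> None:
    path = Path(path)
    table.values.to_csv(path, sep=_sep_for(path, dialect), index_label="phage",
                        na_rep="NA")


def read_partition(path: str | Path) -> Partition:
    """Read a partition from JSON ({item: label}) or two-column TSV (item, label)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict) and "labels" in data:
            data = data["labels"]
        return Partition.from_dict(data)
    df = pd.read_csv(path, sep=_sep_for(path, None), dtype=str)
    if not {"item", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: partition table needs columns ['item', 'label']")
    return Partition(list(df["item"]), list(df["label"]))


def write_partition(p: Partition, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"labels": p.as_dict()}, fh, indent=2)
            fh.write("\n")
    else:
        pd.DataFrame({"item": p.item_ids, "label": p.labels}).to_csv(
            path, sep="\t", index=False
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree; every non-root edge needs a branch length."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon" in str(exc) or "duplicate" in str(exc).lower():
            raise ValueError(f"{path}: duplicate leaf labels in tree: {exc}") from exc
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValueError(f"{path}: tree contains an unlabeled leaf")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate leaf labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError(
                f"{path}: missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'an internal node'!r}"
            )
    return tree
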