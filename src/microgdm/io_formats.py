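"""Readers, writers, and validated domain types for on-disk artifacts.

Every table is UTF-8 TSV. Trees are newick. All readers validate strictly
and report the offending row/column instead of silently coercing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "ValidationError",
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "PhyloTree",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

MISSING_TOKEN = "NA"

_INT_RE = re.compile(r"^[+-]?\d+$")


class FormatError(ValueError):
    """File cannot be parsed at all (bad header, ragged rows, bad newick)."""


class ValidationError(ValueError):
    """File parses but violates a domain invariant (duplicate id, negative count)."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Integer count matrix, samples x features, with identifiers.

    ``counts[i, j]`` is the number of reads of feature ``feature_ids[j]``
    observed in sample ``sample_ids[i]``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                np.mod(self.counts[np.isfinite(self.counts)], 1) == 0
            ):
                if np.any(~np.isfinite(self.counts)):
                    raise ValidationError("counts contain non-finite entries")
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers")
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized proportions; all-zero rows map to zero rows."""
        d = self.depths().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / d[:, None]
        p[d == 0] = 0.0
        return p

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.feature_ids), self.counts[idx])

    def select_features(self, feature_ids) -> "OtuTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return OtuTable(list(self.sample_ids), list(feature_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="#SampleID"),
            columns=self.feature_ids,
        )


@dataclass
class TaxonomyMap:
    """feature_id -> 7-rank lineage (kingdom..species); '' marks unassigned ranks."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        fixed = {}
        for fid, lin in self.lineages.items():
            lin = tuple(str(x) for x in lin)
            if len(lin) > len(RANKS):
                raise ValidationError(
                    f"lineage for {fid!r} has {len(lin)} ranks, max {len(RANKS)}"
                )
            lin = lin + ("",) * (len(RANKS) - len(lin))
            fixed[str(fid)] = lin
        self.lineages = fixed

    def lineage_at(self, feature_id: str, rank: str) -> str:
        """Lineage prefix string down to ``rank``; '' components mean unassigned."""
        k = RANKS.index(rank)
        return ";".join(self.lineages[feature_id][: k + 1])

    def name_at(self, feature_id: str, rank: str) -> str:
        return self.lineages[feature_id][RANKS.index(rank)]

    def check_covers(self, table: OtuTable) -> None:
        missing = [f for f in table.feature_ids if f not in self.lineages]
        if missing:
            raise ValidationError(
                f"taxonomy missing {len(missing)} feature(s), e.g. {missing[0]!r}"
            )


GROUPS = ("case", "control")
SETS = ("discovery", "validation")


@dataclass
class SampleMetadata:
    """Per-sample group / pair / set assignment plus typed clinical indices.

    ``frame`` is indexed by sample id with columns ``group``, ``pair_id``,
    ``set`` and one float column per clinical index (NaN = missing).
    """

    frame: pd.DataFrame
    clinical_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(list(f.index), "sample")
        for col in ("group", "set"):
            if col not in f.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad = set(f["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group level(s): {sorted(bad)}")
        bad = set(f["set"]) - set(SETS)
        if bad:
            raise ValidationError(f"unknown set level(s): {sorted(bad)}")
        self.clinical_columns = tuple(self.clinical_columns)
        for col in self.clinical_columns:
            if col not in f.columns:
                raise ValidationError(f"declared clinical column {col!r} absent")
            f[col] = pd.to_numeric(f[col], errors="raise").astype(float)
        if "pair_id" in f.columns:
            paired = f[f["pair_id"].notna() & (f["pair_id"] != "")]
            for pid, sub in paired.groupby("pair_id"):
                groups = sorted(sub["group"])
                if groups != ["case", "control"]:
                    raise ValidationError(
                        f"pair {pid!r} must contain exactly one case and one "
                        f"control, got {groups}"
                    )
                if sub["set"].nunique() != 1:
                    raise ValidationError(
                        f"pair {pid!r} spans both discovery and validation sets"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups_for(self, sample_ids) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "group"].to_numpy()

    def samples_in_set(self, which: str) -> list[str]:
        if which not in SETS:
            raise ValidationError(f"unknown set {which!r}")
        return list(self.frame.index[self.frame["set"] == which])

    def n_missing(self) -> int:
        if not self.clinical_columns:
            return 0
        return int(self.frame[list(self.clinical_columns)].isna().sum().sum())


@dataclass
class PhyloTree:
    """Rooted tree with non-negative branch lengths over feature-id leaves."""

    tree: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        _check_unique(names, "leaf")
        for node in self.tree.traverse(include_self=False):
            if node.length is None or not np.isfinite(node.length):
                raise ValidationError(
                    f"branch above {node.name or '<internal>'} has no finite length"
                )
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length above {node.name or '<internal>'}"
                )

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))
        )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with a zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        _check_unique(self.sample_ids, "sample")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(self.d < -1e-10):
            raise ValidationError("distances must be non-negative")
        self.d = np.maximum((self.d + self.d.T) / 2.0, 0.0)
        np.fill_diagonal(self.d, 0.0)


# ---------------------------------------------------------------------------
# OTU table I/O


def read_otu_table(path, orientation: str = "samples-as-rows") -> OtuTable:
    """Read a TSV count table.

    ``orientation`` must be given explicitly ('samples-as-rows' or
    'features-as-rows'); auto-detection is deliberately not offered.
    """
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.hasnans or any(pd.isna(c) for c in df.columns):
        raise FormatError(f"{path}: malformed header (empty id)")
    counts = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = values[i, j]
            if not isinstance(tok, str) or not _INT_RE.match(tok.strip()):
                raise ValidationError(
                    f"{path}: non-integer count {tok!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
            counts[i, j] = int(tok)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if orientation == "features-as-rows":
        return OtuTable(cols, rows, counts.T)
    return OtuTable(rows, cols, counts)


def write_otu_table(table: OtuTable, path, orientation: str = "samples-as-rows") -> None:
    df = table.to_frame()
    if orientation == "features-as-rows":
        df = df.T
        df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy I/O


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV: feature id, semicolon-joined lineage."""
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty taxonomy file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            fid, lineage = parts
            if fid in lineages:
                raise ValidationError(f"{path}: line {lineno}: duplicate feature {fid!r}")
            lineages[fid] = tuple(x.strip() for x in lineage.split(";"))
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, lin in tax.lineages.items():
            fh.write(f"{fid}\t{';'.join(lin)}\n")


# ---------------------------------------------------------------------------
# Metadata I/O


def read_metadata(path, clinical_columns=()) -> SampleMetadata:
    """Read sample metadata; ``NA`` cells in clinical columns become missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    clinical_columns = tuple(clinical_columns)
    for col in clinical_columns:
        if col not in df.columns:
            raise ValidationError(f"{path}: declared clinical column {col!r} absent")
        raw = df[col]
        vals = np.full(len(raw), np.nan)
        for i, tok in enumerate(raw):
            if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                continue
            tok = str(tok).strip()
            if tok == MISSING_TOKEN or tok == "":
                continue
            try:
                vals[i] = float(tok)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric clinical value {tok!r} at sample "
                    f"{df.index[i]!r}, column {col!r}"
                ) from exc
        df[col] = vals
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].fillna("")
    return SampleMetadata(df, clinical_columns)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    for col in meta.clinical_columns:
        df[col] = [
            MISSING_TOKEN if pd.isna(v) else np.format_float_positional(v, trim="-")
            for v in df[col]
        ]
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Tree I/O


def read_tree(path, missing_length: str = "error") -> PhyloTree:
    """Read a rooted newick tree.

    missing_length: 'error' rejects branches without lengths; 'zero' assigns
    0.0 with a warning.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse newick {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_length == "zero":
                node.length = 0.0
                n_missing += 1
            else:
                raise ValidationError(
                    f"{path}: branch above {node.name or '<internal>'} lacks a length"
                )
    if n_missing:
        warnings.warn(f"{path}: assigned length 0 to {n_missing} branch(es)")
    return PhyloTree(tree)


def write_tree(ptree: PhyloTree, path) -> None:
    ptree.tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Distance matrix I/O


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column ids differ")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.d, index=dm.sample_ids, columns=dm.sample_ids)
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")
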