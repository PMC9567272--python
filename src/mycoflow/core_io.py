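"""Data model and I/O for low-biomass amplicon feature tables.

The package works on taxa-by-sample count matrices (ITS2 fungal amplicons and
matched bacterial tables), per-sample metadata describing sample class
(tissue vs. negative control), condition, sequencing library and dilution,
and signed co-occurrence edge lists. Tables are carried around as a
:class:`FeatureTable`, a thin wrapper over a dense pandas DataFrame with
taxonomy and provenance attached; all tables here are small (at most a few
thousand features), so sparse storage buys nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Taxonomic ranks from coarsest to finest, excluding the ASV level.
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)
RANK_PREFIXES: dict[str, str] = {
    "kingdom": "k", "phylum": "p", "class": "c", "order": "o",
    "family": "f", "genus": "g", "species": "s",
}
#: Sentinel used for ranks below the lowest classified one.
OTHER = "Other"

TABLE_STATES = ("raw", "floored", "floored_normalized", "unfloored_normalized")
LEVELS = ("ASV",) + RANKS
SAMPLE_CLASSES = ("tissue", "extraction_control", "paraffin_control")
CONTROL_CLASSES = ("extraction_control", "paraffin_control")


class ValidationError(ValueError):
    """Raised when a table, metadata file, or network fails validation."""


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyLineage:
    """A UNITE-style lineage with unknown ranks replaced by ``Other``.

    ``ranks`` maps every rank in :data:`RANKS` to a name; ranks below
    ``lowest_known_rank`` carry the :data:`OTHER` sentinel. The kingdom is
    always present.
    """

    ranks: tuple[tuple[str, str], ...]
    lowest_known_rank: str

    def __post_init__(self):
        names = dict(self.ranks)
        if set(names) != set(RANKS):
            raise ValidationError(f"lineage must define all ranks, got {list(names)}")
        if names["kingdom"] in ("", OTHER):
            raise ValidationError("kingdom must be a known name")
        seen_known = True
        for rank in RANKS:
            if rank == self.lowest_known_rank:
                seen_known = False
                continue
            if not seen_known and names[rank] != OTHER:
                raise ValidationError(
                    f"rank {rank} below lowest_known_rank must be {OTHER!r}"
                )

    @property
    def names(self) -> dict[str, str]:
        return dict(self.ranks)

    def name_at(self, rank: str) -> str:
        return dict(self.ranks)[rank]

    @classmethod
    def from_names(cls, names: dict[str, str]) -> "TaxonomyLineage":
        """Build a lineage from possibly-partial rank names.

        Missing or empty entries become ``Other``; the lowest contiguously or
        non-contiguously known rank is the deepest rank with a real name.
        """
        filled: dict[str, str] = {}
        lowest = "kingdom"
        for rank in RANKS:
            name = (names.get(rank) or "").strip()
            if name and name != OTHER:
                filled[rank] = name
                lowest = rank
            else:
                filled[rank] = OTHER
        if filled["kingdom"] == OTHER:
            raise ValidationError("kingdom missing from lineage")
        # Everything below the deepest known rank is Other by construction;
        # gaps above it are also rendered Other but do not move the pointer.
        below = False
        for rank in RANKS:
            if below:
                filled[rank] = OTHER
            if rank == lowest:
                below = True
        return cls(ranks=tuple(filled.items()), lowest_known_rank=lowest)

    @classmethod
    def from_string(cls, lineage: str, fallback_kingdom: str = "Unassigned"
                    ) -> "TaxonomyLineage":
        """Parse ``k__Fungi;p__Ascomycota;...;s__`` strings.

        An unparseable string yields a kingdom-only lineage (with
        ``fallback_kingdom``) and a logged warning rather than an error.
        """
        names: dict[str, str] = {}
        ok = False
        for token in str(lineage).split(";"):
            token = token.strip()
            if "__" not in token:
                continue
            prefix, _, name = token.partition("__")
            prefix = prefix.strip().lower()
            for rank, p in RANK_PREFIXES.items():
                if prefix == p:
                    names[rank] = name.strip().replace("_", " ") if rank == "species" else name.strip()
                    ok = True
        if not ok or not names.get("kingdom"):
            logger.warning(
                "unparseable lineage %r; keeping kingdom-only (%s)",
                lineage, fallback_kingdom,
            )
            names = {"kingdom": names.get("kingdom") or fallback_kingdom}
        return cls.from_names(names)

    def to_string(self, down_to: str = "species") -> str:
        stop = RANKS.index(down_to)
        parts = []
        for rank in RANKS[: stop + 1]:
            name = self.name_at(rank)
            parts.append(f"{RANK_PREFIXES[rank]}__{'' if name == OTHER else name}")
        return ";".join(parts)

    def truncate(self, level: str) -> "TaxonomyLineage":
        """Lineage with every rank below ``level`` forced to ``Other``."""
        idx = RANKS.index(level)
        names = {r: (self.name_at(r) if i <= idx else OTHER)
                 for i, r in enumerate(RANKS)}
        lowest = "kingdom"
        for i, r in enumerate(RANKS[: idx + 1]):
            if names[r] != OTHER:
                lowest = r
        return TaxonomyLineage(ranks=tuple(names.items()), lowest_known_rank=lowest)

    def group_id(self, level: str) -> str:
        """Aggregated feature id at ``level``.

        Known ranks keep their name; unknown ranks at or above ``level`` are
        rendered as ``Other`` suffixed to the lowest known name, e.g.
        ``...;g__Cladosporium;s__Other``.
        """
        idx = RANKS.index(level)
        parts = []
        for rank in RANKS[: idx + 1]:
            name = self.name_at(rank)
            parts.append(f"{RANK_PREFIXES[rank]}__{name}")
        return ";".join(parts)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Taxa-by-samples count matrix with taxonomy and provenance.

    ``counts`` is features (rows) x samples (columns). Raw tables hold
    integers; normalized tables may be fractional. ``state`` tracks where
    the table sits in the flooring/normalization pipeline and ``provenance``
    records the parameters applied (e.g. the flooring threshold).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyLineage] | None = None
    state: str = "raw"
    level: str = "ASV"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence (count > 0) matrix."""
        return self.counts > 0

    def total_reads(self) -> float:
        return float(self.counts.to_numpy().sum())

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.state not in TABLE_STATES:
            raise ValidationError(f"unknown table state {self.state!r}")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown taxonomic level {self.level!r}")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dupes)}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes)}")
        values = self.counts.to_numpy()
        if values.size and (np.asarray(values) < 0).any():
            raise ValidationError("negative counts")
        if self.taxonomy is not None:
            extra = set(self.taxonomy) - set(self.counts.index)
            if extra:
                raise ValidationError(f"taxonomy keys not in table: {sorted(extra)}")
        if self.state == "floored":
            thr = self.provenance.get("floor_threshold")
            if thr is not None and values.size:
                bad = (values > 0) & (values < thr)
                if bad.any():
                    raise ValidationError(
                        "floored table has entries strictly between 0 and "
                        f"the floor threshold {thr}"
                    )

    def replace(self, counts: pd.DataFrame | None = None, **kwargs) -> "FeatureTable":
        """Copy of this table with selected fields replaced."""
        return FeatureTable(
            counts=self.counts.copy() if counts is None else counts,
            taxonomy=kwargs.get("taxonomy", dict(self.taxonomy) if self.taxonomy else None),
            state=kwargs.get("state", self.state),
            level=kwargs.get("level", self.level),
            provenance=kwargs.get("provenance", dict(self.provenance)),
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"samples not in table: {sorted(missing)}")
        return self.replace(counts=self.counts.loc[:, list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.upper()
    return "BIOM" if path.suffix.lower() == ".biom" else "TSV"


def read_feature_table(path, format: str | None = None) -> FeatureTable:
    """Read a feature table from BIOM 2.x (HDF5/JSON) or TSV.

    TSV dialect: tab-separated, UTF-8, lines starting with ``#`` ignored,
    features as rows and samples as columns, with an optional trailing
    ``taxonomy`` column of UNITE-style lineage strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "BIOM":
        return _read_biom(path)
    if fmt == "TSV":
        return _read_tsv(path)
    raise ValueError(f"unknown table format {fmt!r}")


def _read_biom(path: Path) -> FeatureTable:
    import biom

    bt = biom.load_table(str(path))
    counts = pd.DataFrame(
        bt.matrix_data.toarray(),
        index=list(bt.ids("observation")),
        columns=list(bt.ids("sample")),
    )
    taxonomy = None
    md = bt.metadata(axis="observation")
    if md is not None:
        taxonomy = {}
        for fid, meta in zip(counts.index, md):
            tax = (meta or {}).get("taxonomy")
            if tax is None:
                continue
            if not isinstance(tax, str):
                tax = ";".join(tax)
            taxonomy[fid] = TaxonomyLineage.from_string(tax)
        if not taxonomy:
            taxonomy = None
    if (counts.to_numpy() % 1 == 0).all():
        counts = counts.astype(np.int64)
    return FeatureTable(counts=counts, taxonomy=taxonomy)


def _read_tsv(path: Path) -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty table")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    taxonomy = None
    if "taxonomy" in df.columns:
        tax_col = df.pop("taxonomy")
        taxonomy = {
            str(fid): TaxonomyLineage.from_string(s)
            for fid, s in tax_col.items()
            if isinstance(s, str) and s.strip()
        } or None
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric counts ({exc})") from exc
    if (values.to_numpy() % 1 == 0).all():
        values = values.astype(np.int64)
    return FeatureTable(counts=values, taxonomy=taxonomy)


def write_feature_table(table: FeatureTable, path, format: str | None = None) -> None:
    """Write a feature table as BIOM 2.x (HDF5) or TSV (round-trip safe)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "BIOM":
        import biom
        from biom.util import biom_open

        obs_md = None
        if table.taxonomy:
            obs_md = [
                {"taxonomy": table.taxonomy[fid].to_string().split(";")}
                if fid in table.taxonomy else {"taxonomy": None}
                for fid in table.feature_ids
            ]
        bt = biom.Table(
            table.counts.to_numpy(dtype=float),
            observation_ids=table.feature_ids,
            sample_ids=table.sample_ids,
            observation_metadata=obs_md,
        )
        with biom_open(str(path), "w") as fh:
            bt.to_hdf5(fh, "mycoflow")
    elif fmt == "TSV":
        df = table.counts.copy()
        if table.taxonomy:
            df["taxonomy"] = [
                table.taxonomy[fid].to_string() if fid in table.taxonomy else ""
                for fid in table.feature_ids
            ]
        df.to_csv(path, sep="\t", index_label="feature_id")
    else:
        raise ValueError(f"unknown table format {fmt!r}")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "sample_class", "condition", "library_id",
                    "dilution_factor")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate per-sample metadata from TSV.

    Required columns: sample_id, sample_class, condition, library_id,
    dilution_factor. Missing dilution factors default to 1. Unknown sample
    classes are a hard error naming the offending rows.
    """
    path = Path(path)
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "library_id": str},
                     comment=None)
    return validate_metadata(md)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    md = md.copy()
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        dupes = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    bad = ~md["sample_class"].isin(SAMPLE_CLASSES)
    if bad.any():
        rows = md.loc[bad, ["sample_id", "sample_class"]]
        raise ValidationError(
            "unknown sample_class values: "
            + "; ".join(f"{r.sample_id}={r.sample_class!r}" for r in rows.itertuples())
        )
    md["condition"] = md["condition"].fillna("").astype(str)
    md["dilution_factor"] = pd.to_numeric(
        md["dilution_factor"], errors="coerce"
    ).fillna(1.0)
    if (md["dilution_factor"] <= 0).any():
        rows = md.loc[md["dilution_factor"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive dilution_factor for samples: {rows}")
    return md.set_index("sample_id", drop=False)


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index=False)


def check_table_metadata(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Every sample in the table must have a metadata row."""
    missing = set(table.sample_ids) - set(metadata.index)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Co-occurrence networks
# ---------------------------------------------------------------------------

EDGE_CLASSES = ("FF", "BB", "FB")


@dataclass(frozen=True)
class NmiEdge:
    """A retained, signed co-occurrence edge between two taxa."""

    source: str
    target: str
    edge_class: str  # FF, BB or FB
    nmi: float
    p: float
    q: float
    sign: str  # "+" or "-"

    def __post_init__(self):
        if self.edge_class not in EDGE_CLASSES:
            raise ValidationError(f"unknown edge class {self.edge_class!r}")
        if self.sign not in ("+", "-"):
            raise ValidationError(f"edge sign must be '+' or '-', got {self.sign!r}")
        if self.source == self.target:
            raise ValidationError("self-edges are not allowed")


@dataclass
class NmiNetwork:
    """FDR-filtered edge lists for one tissue (FF, BB and FB classes)."""

    edges: list[NmiEdge]
    tissue: str = ""
    n_shuffles: int = 0
    fdr_threshold: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e.q > self.fdr_threshold + 1e-12:
                raise ValidationError(
                    f"edge {e.source}--{e.target} has q={e.q} above the "
                    f"FDR threshold {self.fdr_threshold}"
                )
            key = frozenset((e.source, e.target))
            if key in seen:
                raise ValidationError(f"duplicate edge {e.source}--{e.target}")
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges, key=lambda e: (e.source, e.target))
        return pd.DataFrame(
            [(e.source, e.target, e.edge_class, e.nmi, e.p, e.q, e.sign)
             for e in rows],
            columns=["source", "target", "edge_class", "nmi", "p", "q", "sign"],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(tissue=self.tissue)
        for e in self.edges:
            g.add_edge(e.source, e.target, edge_class=e.edge_class,
                       nmi=e.nmi, p=e.p, q=e.q, sign=e.sign)
        return g


def write_network(network: NmiNetwork, path) -> None:
    """Serialize a network as a TSV edge list (deterministic row order)."""
    network.to_frame().to_csv(path, sep="\t", index=False)


def read_network(path, tissue: str = "", fdr_threshold: float = 0.2,
                 n_shuffles: int = 0) -> NmiNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [
        NmiEdge(source=str(r.source), target=str(r.target),
                edge_class=r.edge_class, nmi=float(r.nmi), p=float(r.p),
                q=float(r.q), sign=r.sign)
        for r in df.itertuples()
    ]
    return NmiNetwork(edges=edges, tissue=tissue,
                      fdr_threshold=fdr_threshold, n_shuffles=n_shuffles)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds and paths, mirrored by the CLI flags."""

    floor_threshold: int = 1000
    alpha: float = 0.05
    fdr: float = 0.2
    n_shuffles: int = 1000
    pseudocount: float = 1.0
    seed: int | None = None
    level: str = "species"
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.floor_threshold < 1:
            raise ValidationError("floor_threshold must be >= 1")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown taxonomic level {self.level!r}")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for stochastic operations")
        return int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
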