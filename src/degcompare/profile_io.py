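"""Reading, weaving and writing differential-expression result tables.

A *profile* is the result table of one differential-expression contrast:
one row per gene with a log2 fold change (logFC) and an FDR-adjusted
p-value (padj).  Profiles from heterogeneous experiments are woven into a
wide *master table* (gene x experiment), from which per-experiment DEG
lists are called at a significance threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentProfile",
    "MasterTable",
    "DEGListSet",
    "ProfileIOError",
    "ConfigurationError",
    "ParseError",
    "read_result_table",
    "weave",
    "split",
    "call_degs",
    "write_outputs",
    "write_master",
    "read_master",
]


class ProfileIOError(ValueError):
    """Base class for malformed inputs or configuration."""


class ConfigurationError(ProfileIOError):
    """Requested columns/dialect cannot be resolved against the file."""


class ParseError(ProfileIOError):
    """A cell could not be parsed as a number."""


# Column-name candidates per dialect.  "limma-style" matches the export of
# limma::topTable (logFC / adj.P.Val); "deseq2-style" matches
# DESeq2::results written to disk (log2FoldChange / padj, gene IDs in the
# first, typically unnamed, column); "generic" tries common spellings.
_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "generic": {
        "id": ("gene_id", "gene", "id", "ID", "GeneID"),
        "logfc": ("logFC", "log2FoldChange", "logfc", "log2FC", "LFC"),
        "padj": ("padj", "adj.P.Val", "FDR", "qvalue", "adj_p"),
    },
    "limma-style": {
        "id": ("ID",),
        "logfc": ("logFC",),
        "padj": ("adj.P.Val",),
    },
    "deseq2-style": {
        "id": (),  # first (unnamed) column
        "logfc": ("log2FoldChange",),
        "padj": ("padj",),
    },
}


@dataclass
class ExperimentProfile:
    """One experiment's differential-expression result.

    ``data`` is indexed by gene ID with float columns ``logfc`` (never
    missing) and ``padj`` (may be NaN, e.g. genes removed by the upstream
    tool's independent filtering — those genes are measured but can never
    be called significant).
    """

    experiment_id: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.experiment_id:
            raise ProfileIOError("experiment_id must be non-empty")
        if list(self.data.columns) != ["logfc", "padj"]:
            self.data = self.data[["logfc", "padj"]]
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ProfileIOError(
                f"duplicate gene IDs in profile {self.experiment_id!r}: {dups}"
            )
        padj = self.data["padj"]
        bad = padj.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ProfileIOError(
                f"padj outside [0, 1] in profile {self.experiment_id!r}"
            )

    @classmethod
    def from_records(
        cls,
        experiment_id: str,
        records: Mapping[str, tuple[float, float | None]],
        metadata: dict | None = None,
    ) -> "ExperimentProfile":
        """Build a profile from a gene -> (logfc, padj) mapping."""
        idx = pd.Index(list(records), name="gene_id")
        logfc = [records[g][0] for g in idx]
        padj = [np.nan if records[g][1] is None else records[g][1] for g in idx]
        df = pd.DataFrame({"logfc": logfc, "padj": padj}, index=idx, dtype=float)
        return cls(experiment_id, df, metadata or {})

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MasterTable:
    """Gene x experiment matrices of logFC and adjusted p-values.

    A NaN in ``logfc`` means the gene was not measured in that experiment
    (e.g. absent from the platform); ``padj`` is then NaN as well.  A NaN
    in ``padj`` with a finite logFC is a measured gene whose adjusted p
    was reported as NA upstream.
    """

    logfc: pd.DataFrame
    padj: pd.DataFrame

    def __post_init__(self) -> None:
        if self.logfc.shape != self.padj.shape:
            raise ProfileIOError("logfc and padj matrices differ in shape")
        if not self.logfc.index.equals(self.padj.index):
            raise ProfileIOError("logfc and padj gene indices differ")
        if not self.logfc.columns.equals(self.padj.columns):
            raise ProfileIOError("logfc and padj experiment columns differ")
        if self.logfc.index.has_duplicates:
            raise ProfileIOError("duplicate gene IDs in master table")
        if self.logfc.columns.has_duplicates:
            raise ProfileIOError("duplicate experiment IDs in master table")
        # padj present => logfc present
        if (self.padj.notna() & self.logfc.isna()).any().any():
            raise ProfileIOError("padj present for an unmeasured (logfc-NaN) cell")

    @property
    def gene_ids(self) -> pd.Index:
        return self.logfc.index

    @property
    def experiments(self) -> list[str]:
        return list(self.logfc.columns)

    @property
    def measured(self) -> pd.DataFrame:
        """Boolean gene x experiment mask of measured cells."""
        return self.logfc.notna()


@dataclass
class DEGListSet:
    """Per-experiment DEG sets at a fixed threshold, plus their union.

    ``union`` is the joint DEG list A (genes significant in >= 1 list);
    ``N`` its size; ``m`` the number of retained lists.
    """

    lists: dict[str, frozenset[str]]
    alpha: float
    min_abs_logfc: float = 0.0

    def __post_init__(self) -> None:
        for exp, genes in self.lists.items():
            if len(genes) == 0:
                raise ProfileIOError(f"empty DEG list for {exp!r}; drop it first")

    @property
    def union(self) -> frozenset[str]:
        return frozenset().union(*self.lists.values()) if self.lists else frozenset()

    @property
    def N(self) -> int:
        return len(self.union)

    @property
    def m(self) -> int:
        return len(self.lists)

    @property
    def experiments(self) -> list[str]:
        return list(self.lists)

    def sizes(self) -> dict[str, int]:
        return {exp: len(genes) for exp, genes in self.lists.items()}

    def membership_counts(self) -> dict[str, int]:
        """For every union gene, the number of lists containing it."""
        counts: dict[str, int] = {}
        for genes in self.lists.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# reading


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _resolve_column(
    columns: Sequence[str], explicit: str | None, candidates: tuple[str, ...], role: str
) -> str | None:
    if explicit is not None:
        if explicit not in columns:
            raise ConfigurationError(
                f"column {explicit!r} (for {role}) not found; file has {list(columns)}"
            )
        return explicit
    for cand in candidates:
        if cand in columns:
            return cand
    return None


def read_result_table(
    path: str | Path,
    dialect: str = "generic",
    *,
    experiment_id: str | None = None,
    id_column: str | None = None,
    logfc_column: str | None = None,
    padj_column: str | None = None,
    delimiter: str | None = None,
    collapse_duplicates: bool = False,
    metadata: dict | None = None,
) -> ExperimentProfile:
    """Read one exported DE result table into an :class:`ExperimentProfile`.

    Parameters
    ----------
    dialect
        ``"generic"``, ``"limma-style"`` (topTable export) or
        ``"deseq2-style"`` (results export, IDs in the first unnamed
        column).  Explicit ``*_column`` names override the dialect.
    collapse_duplicates
        When True, duplicated gene IDs are collapsed keeping the row with
        the smallest padj (ties: largest \\|logFC\\|, then first occurrence)
        instead of raising.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}"
        )
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    spec = _DIALECTS[dialect]

    idc = _resolve_column(cols, id_column, spec["id"], "gene ID")
    if idc is None:
        # IDs live in the first column (deseq2-style unnamed index, or a
        # generic file whose first column is unrecognized).
        idc = cols[0]
    lfc = _resolve_column(cols, logfc_column, spec["logfc"], "logFC")
    if lfc is None:
        raise ConfigurationError(
            f"no logFC column among {cols} for dialect {dialect!r}"
        )
    pjc = _resolve_column(cols, padj_column, spec["padj"], "adjusted p")
    if pjc is None:
        raise ConfigurationError(
            f"no adjusted-p column among {cols} for dialect {dialect!r}"
        )

    def _numeric(col: str, allow_missing: bool) -> pd.Series:
        s = raw[col].str.strip()
        missing = s.isin(["", "NA", "NaN", "nan", "N/A", "null"])
        out = pd.to_numeric(s.mask(missing), errors="coerce")
        bad = out.isna() & ~missing
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(
                f"non-numeric value {s[bad].iloc[0]!r} in column {col!r} "
                f"of {path.name}, line {row}"
            )
        if not allow_missing and missing.any():
            row = int(np.flatnonzero(missing.to_numpy())[0]) + 2
            logger.warning(
                "%s: dropping %d row(s) with missing %s (first at line %d)",
                path.name, int(missing.sum()), col, row,
            )
        return out

    df = pd.DataFrame(
        {
            "logfc": _numeric(lfc, allow_missing=False).to_numpy(),
            "padj": _numeric(pjc, allow_missing=True).to_numpy(),
        },
        index=pd.Index(raw[idc].str.strip(), name="gene_id"),
    )
    df = df[df["logfc"].notna()]

    if df.index.has_duplicates:
        if not collapse_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ProfileIOError(f"duplicate gene IDs in {path.name}: {dups}")
        df = _collapse_duplicates(df)

    exp_id = experiment_id or path.stem.split(".")[0]
    return ExperimentProfile(exp_id, df, metadata or {})


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene, the row with smallest padj; ties by largest |logFC|,
    then first occurrence.  NaN padj sorts last."""
    order = df.assign(
        _padj=df["padj"].fillna(np.inf),
        _neg_abs=-df["logfc"].abs(),
        _pos=np.arange(len(df)),
    ).sort_values(["_padj", "_neg_abs", "_pos"], kind="stable")
    kept = order[~order.index.duplicated(keep="first")]
    return kept.loc[df.index.unique(), ["logfc", "padj"]]


# ---------------------------------------------------------------------------
# weaving


def weave(profiles: Sequence[ExperimentProfile]) -> MasterTable:
    """Assemble profiles into a master table over the union of their genes.

    Gene order is first-seen across profiles; cells for genes absent from
    a profile are missing (NaN in both matrices).
    """
    if len(profiles) == 0:
        raise ProfileIOError("no profiles to weave")
    ids = [p.experiment_id for p in profiles]
    if len(set(ids)) != len(ids):
        dups = [i for n, i in enumerate(ids) if i in ids[:n]]
        raise ProfileIOError(f"duplicate experiment_ids: {sorted(set(dups))}")
    if len(profiles) < 2:
        raise ProfileIOError("weave needs at least 2 profiles")

    gene_order: list[str] = []
    seen_genes: set[str] = set()
    for p in profiles:
        for g in p.genes:
            if g not in seen_genes:
                seen_genes.add(g)
                gene_order.append(g)
    idx = pd.Index(gene_order, name="gene_id")
    logfc = pd.DataFrame(
        {p.experiment_id: p.data["logfc"].reindex(idx) for p in profiles}
    )
    padj = pd.DataFrame(
        {p.experiment_id: p.data["padj"].reindex(idx) for p in profiles}
    )
    return MasterTable(logfc, padj)


def split(master: MasterTable) -> list[ExperimentProfile]:
    """Inverse of :func:`weave`: one profile per experiment, unmeasured
    genes dropped."""
    out = []
    for exp in master.experiments:
        df = pd.DataFrame(
            {"logfc": master.logfc[exp], "padj": master.padj[exp]}
        )
        df = df[df["logfc"].notna()]
        df.index.name = "gene_id"
        out.append(ExperimentProfile(exp, df))
    return out


# ---------------------------------------------------------------------------
# DEG calling


def call_degs(
    master: MasterTable,
    alpha: float = 0.05,
    min_abs_logfc: float = 0.0,
    *,
    inclusive: bool = False,
) -> DEGListSet:
    """Call per-experiment DEG lists: padj < alpha (or <= with
    ``inclusive``) and \\|logFC\\| >= ``min_abs_logfc``.

    Genes with missing padj are never DEGs.  Experiments with zero DEGs
    are dropped with a warning; lists with fewer than 10 DEGs are retained
    but flagged, as descriptive indicators are unstable for tiny lists.
    """
    if not (0.0 < alpha < 1.0):
        raise ProfileIOError(f"alpha must be in (0, 1), got {alpha}")
    if min_abs_logfc < 0:
        raise ProfileIOError("min_abs_logfc must be >= 0")
    padj = master.padj
    sig = padj.le(alpha) if inclusive else padj.lt(alpha)
    sig &= padj.notna()
    if min_abs_logfc > 0:
        sig &= master.logfc.abs().ge(min_abs_logfc)

    lists: dict[str, frozenset[str]] = {}
    for exp in master.experiments:
        genes = frozenset(sig.index[sig[exp].to_numpy(dtype=bool)])
        if not genes:
            logger.warning("experiment %s has 0 DEGs at alpha=%g; dropped", exp, alpha)
            continue
        if len(genes) < 10:
            logger.warning(
                "experiment %s has only %d DEGs (<10); indicators may be unstable",
                exp, len(genes),
            )
        lists[exp] = genes
    if not lists:
        raise ProfileIOError(f"no DEGs at alpha={alpha} in any experiment")
    return DEGListSet(lists, alpha, min_abs_logfc)


# ---------------------------------------------------------------------------
# writing


def write_master(master: MasterTable, path: str | Path) -> None:
    """Write the wide master-table format: gene_id, then per experiment the
    column pair ``<exp>_logFC`` and ``<exp>_padj``."""
    out = pd.DataFrame(index=master.gene_ids)
    for exp in master.experiments:
        out[f"{exp}_logFC"] = master.logfc[exp]
        out[f"{exp}_padj"] = master.padj[exp]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_master(path: str | Path) -> MasterTable:
    """Read the wide master-table format written by :func:`write_master`."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = "gene_id"
    exps: list[str] = []
    for col in raw.columns:
        if col.endswith("_logFC"):
            exps.append(col[: -len("_logFC")])
    missing = [e for e in exps if f"{e}_padj" not in raw.columns]
    if missing:
        raise ConfigurationError(f"master table lacks padj columns for {missing}")
    if not exps:
        raise ConfigurationError(
            "no <experiment>_logFC column pairs found in master table"
        )
    logfc = pd.DataFrame({e: raw[f"{e}_logFC"].astype(float) for e in exps})
    padj = pd.DataFrame({e: raw[f"{e}_padj"].astype(float) for e in exps})
    return MasterTable(logfc, padj)


def _sorted_gene_table(
    genes: Iterable[str], master: MasterTable, exp: str
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": sorted(genes),
        }
    ).set_index("gene_id")
    df["logFC"] = master.logfc.loc[df.index, exp]
    df["padj"] = master.padj.loc[df.index, exp]
    df = df.sort_values(["padj", "gene_id"], kind="stable", na_position="last")
    return df.reset_index()


def write_outputs(
    degset: DEGListSet, master: MasterTable, outdir: str | Path
) -> dict[str, str]:
    """Write per-experiment DEG and specific-DEG tables, the union table,
    and a JSON run manifest.  Returns the file inventory (name -> path).

    Row order is deterministic: ascending padj then gene ID within each
    experiment table; descending membership count then gene ID in the
    union table.  Re-running on identical input yields identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = degset.membership_counts()
    inventory: dict[str, str] = {}

    for exp, genes in degset.lists.items():
        degs = _sorted_gene_table(genes, master, exp)
        p = outdir / f"{exp}.degs.tsv"
        degs.to_csv(p, sep="\t", index=False)
        inventory[f"{exp}.degs"] = str(p)

        specific = [g for g in genes if counts[g] == 1]
        spec_df = _sorted_gene_table(specific, master, exp)
        p = outdir / f"{exp}.specific.tsv"
        spec_df.to_csv(p, sep="\t", index=False)
        inventory[f"{exp}.specific"] = str(p)

    union_df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "n_lists"],
    )
    p = outdir / "union_degs.tsv"
    union_df.to_csv(p, sep="\t", index=False)
    inventory["union_degs"] = str(p)

    master_bytes = pd.util.hash_pandas_object(
        pd.concat([master.logfc, master.padj], axis=1)
    ).to_numpy().tobytes()
    manifest = {
        "alpha": degset.alpha,
        "min_abs_logfc": degset.min_abs_logfc,
        "experiments": degset.experiments,
        "n_degs": degset.sizes(),
        "union_size": degset.N,
        "master_sha256": hashlib.sha256(master_bytes).hexdigest(),
    }
    p = outdir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    inventory["manifest"] = str(p)
    return inventory
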