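"""File formats and core containers for expression-based immune subtyping.

Supported formats: GCT 1.2 and plain gene x sample TSV for expression,
GMT for gene signatures, TSV for clinical annotation (recurrence-free
survival) and MAF-lite TSV for somatic mutation calls.  All tables are
tab-delimited UTF-8 with '.' decimal separator.

Gene identifiers are uppercased on load by default (``normalize_case``)
because symbol case differs between microarray and RNA-seq platforms;
matching afterwards is case-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("immunophen.io")

__all__ = [
    "ExpressionMatrix",
    "SignatureCollection",
    "ClinicalTable",
    "MutationTable",
    "FormatError",
    "DuplicateGeneError",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "read_mutation_table",
    "load_placeholder_signatures",
    "DEFAULT_NONSYNONYMOUS_CLASSES",
]


class FormatError(ValueError):
    """Malformed input file: bad header, dimension mismatch or unparseable cell."""


class DuplicateGeneError(ValueError):
    """Duplicate gene identifiers encountered under ``duplicate_policy='error'``."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix (FPKM, TPM or array intensity).

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene ids and
    whose columns hold unique sample ids.  Construction validates that no
    missing values remain (imputation/removal happens in the readers) and
    that every cell is numeric.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene ids: {dupes[:5]}")
        if not self.data.columns.is_unique:
            raise ValueError("duplicate sample ids in expression matrix")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:  # non-numeric cell
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        if self.data.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values after load")

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the listed genes (order of ``genes``, absent ones skipped)."""
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])

    def gene_coverage(self, genes: Sequence[str]) -> float:
        """Fraction of ``genes`` present in this matrix."""
        genes = list(genes)
        if not genes:
            return 0.0
        idx = set(self.data.index)
        return sum(g in idx for g in genes) / len(genes)


@dataclass
class SignatureCollection:
    """Named gene sets (GMT semantics): signature name -> list of gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "SignatureCollection":
        names = list(names)
        return SignatureCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with recurrence-free survival.

    ``data`` is indexed by unique sample id and carries at least
    ``rfs_time`` (days, >= 0) and ``rfs_event`` (0/1); ``gleason``,
    ``t_stage`` and ``age`` are optional.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for col in ("rfs_time", "rfs_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate sample ids in clinical table")
        times = self.data["rfs_time"].astype(float)
        if (times < 0).any():
            raise ValueError("negative rfs_time")
        events = self.data["rfs_event"]
        if not events.isin([0, 1]).all():
            raise ValueError("rfs_event must be coded 0/1")
        self.data = self.data.assign(rfs_time=times, rfs_event=events.astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


#: MAF variant classifications counted as nonsynonymous (lowercase match).
DEFAULT_NONSYNONYMOUS_CLASSES = frozenset(
    {
        "missense_mutation",
        "missense",
        "nonsense_mutation",
        "nonsense",
        "nonstop_mutation",
        "frame_shift_del",
        "frame_shift_ins",
        "frameshift",
        "splice_site",
        "in_frame_del",
        "in_frame_ins",
        "in_frame_indel",
        "translation_start_site",
    }
)

#: Classifications recognised as synonymous/non-coding (no warning emitted).
KNOWN_SYNONYMOUS_CLASSES = frozenset(
    {"silent", "synonymous", "3'utr", "5'utr", "intron", "igr", "rna", "3'flank", "5'flank"}
)


@dataclass
class MutationTable:
    """MAF-lite somatic mutation calls: one row per (sample, gene, variant).

    ``covered_megabases`` is the per-sample sequencing footprint used for
    tumor mutation burden; it may be NaN if neither the file nor a default
    supplies it (TMB computation will then refuse to run).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene_id", "is_nonsynonymous"):
            if col not in self.data.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        if "covered_megabases" in self.data.columns:
            mb = self.data["covered_megabases"].dropna()
            if (mb <= 0).any():
                raise ValueError("covered_megabases must be positive")

    def presence_matrix(self, nonsynonymous_only: bool = True) -> pd.DataFrame:
        """Deduplicated samples x genes boolean presence/absence matrix."""
        df = self.data
        if nonsynonymous_only:
            df = df[df["is_nonsynonymous"]]
        if df.empty:
            return pd.DataFrame(dtype=bool)
        return (
            pd.crosstab(df["sample_id"], df["gene_id"]).astype(bool)
        )

    def nonsynonymous_counts(self) -> pd.Series:
        """Nonsynonymous variant count per sample (unique gene-variant rows)."""
        df = self.data[self.data["is_nonsynonymous"]]
        counts = df.groupby("sample_id").size()
        counts.name = "n_nonsynonymous"
        return counts

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


# ---------------------------------------------------------------------------
# expression readers / writers
# ---------------------------------------------------------------------------


def _postprocess_expression(
    df: pd.DataFrame,
    duplicate_policy: str,
    normalize_case: bool,
    max_missing_frac: float,
) -> ExpressionMatrix:
    df = df.apply(pd.to_numeric, errors="coerce")
    # cells that were non-empty text but not numeric are a parse error,
    # distinguished from genuinely empty cells recorded as NaN on read
    if normalize_case:
        df.index = df.index.astype(str).str.strip().str.upper()
    else:
        df.index = df.index.astype(str).str.strip()
    df.index.name = "gene_id"
    df.columns.name = None

    if df.index.duplicated().any():
        if duplicate_policy == "error":
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene ids: {dupes[:5]}")
        elif duplicate_policy == "mean":
            n_before = df.shape[0]
            df = df.groupby(level=0, sort=False).mean()
            logger.info("collapsed %d duplicate gene rows by mean", n_before - df.shape[0])
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    missing_frac = df.isna().mean(axis=1)
    to_drop = missing_frac > max_missing_frac
    if to_drop.any():
        logger.info(
            "dropped %d genes with >%.0f%% missing values",
            int(to_drop.sum()),
            100 * max_missing_frac,
        )
        df = df.loc[~to_drop]
    if df.isna().to_numpy().any():
        n_imputed = int(df.isna().to_numpy().sum())
        medians = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(medians[row.name]), axis=1)
        logger.info("imputed %d missing cells by gene median", n_imputed)
    return ExpressionMatrix(df)


def read_expression(
    path: str | Path,
    format: str = "auto",
    duplicate_policy: str = "mean",
    normalize_case: bool = True,
    max_missing_frac: float = 0.2,
) -> ExpressionMatrix:
    """Read an expression matrix from GCT 1.2 or gene x sample TSV.

    Parameters
    ----------
    format
        ``"gct"``, ``"tsv"`` or ``"auto"`` (by file extension).
    duplicate_policy
        ``"mean"`` collapses duplicate gene rows elementwise (microarray
        probe collapse); ``"error"`` raises :class:`DuplicateGeneError`.
    max_missing_frac
        Genes with a larger fraction of missing cells are dropped; the
        remainder are imputed by gene median.  Both actions are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"

    if format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"GCT must begin with '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise FormatError("GCT missing dimensions line")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise FormatError(f"bad GCT dimensions line: {dims}") from exc
            body = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        if "Description" in body.columns[:1].tolist() or body.columns[0].lower() == "description":
            body = body.drop(columns=body.columns[0])
        if body.shape != (n_genes, n_samples):
            raise FormatError(
                f"GCT declares {n_genes}x{n_samples} but data is {body.shape[0]}x{body.shape[1]}"
            )
        df = body
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & (df.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric expression value {df.iat[r, c]!r} at gene {df.index[r]!r}"
        )
    return _postprocess_expression(numeric, duplicate_policy, normalize_case, max_missing_frac)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, format: str = "auto"
) -> Path:
    """Write an expression matrix as GCT 1.2 or TSV (format by extension)."""
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, expr.sample_ids)) + "\n")
            for gene, row in expr.data.iterrows():
                vals = "\t".join(format_float(v) for v in row.to_numpy())
                fh.write(f"{gene}\tna\t{vals}\n")
    elif format == "tsv":
        out = expr.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return path


def format_float(v: float) -> str:
    return f"{v:.6g}"


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path, normalize_case: bool = True) -> SignatureCollection:
    """Read a GMT file: one signature per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc = fields[0], fields[1]
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if normalize_case:
                genes = [g.upper() for g in genes]
            if not genes:
                raise FormatError(f"{path.name}:{lineno}: signature {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate signature name {name!r}")
            # preserve order, drop repeats within a set
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return SignatureCollection(sets, descriptions)


def write_gene_sets(sigs: SignatureCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sigs.sets.items():
            desc = sigs.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# clinical / mutation tables
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path, time_unit: str = "days") -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, rfs_time, rfs_event.

    Rows with missing time or event are excluded (the count is logged and
    recorded on the returned table).  ``time_unit="months"`` converts to
    days with the 30.44 day average month.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "rfs_time", "rfs_event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing required column {col!r}")
    n_before = len(df)
    df = df.dropna(subset=["rfs_time", "rfs_event"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d clinical rows with missing rfs_time/rfs_event", n_dropped)

    times = pd.to_numeric(df["rfs_time"], errors="coerce")
    if times.isna().any():
        raise FormatError("non-numeric rfs_time value")
    if (times < 0).any():
        raise ValueError("negative rfs_time")
    events = pd.to_numeric(df["rfs_event"], errors="coerce")
    if events.isna().any() or not events.isin([0, 1]).all():
        raise ValueError("rfs_event must be coded strictly as 0/1")
    if time_unit == "months":
        times = times * 30.44
    elif time_unit != "days":
        raise ValueError(f"unknown time_unit {time_unit!r}")

    df = df.assign(rfs_time=times, rfs_event=events.astype(int))
    df = df.set_index("sample_id")
    return ClinicalTable(df, n_dropped=n_dropped)


def read_mutation_table(
    path: str | Path,
    nonsynonymous_classes: Iterable[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    default_megabases: float | None = None,
    normalize_case: bool = True,
) -> MutationTable:
    """Read a MAF-lite TSV (sample_id, gene_id, variant_classification).

    ``is_nonsynonymous`` is derived from the classification whitelist;
    unknown classification strings are warned about and treated as
    synonymous.  An optional ``covered_megabases`` column (or
    ``default_megabases``) supplies the TMB denominator.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "gene_id", "variant_classification"):
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    whitelist = {c.lower() for c in nonsynonymous_classes}
    cls = df["variant_classification"].fillna("").str.strip().str.lower()
    unknown = sorted(set(cls) - whitelist - KNOWN_SYNONYMOUS_CLASSES - {""})
    if unknown:
        logger.warning(
            "unknown variant classifications treated as synonymous: %s", unknown[:10]
        )
    if normalize_case:
        df["gene_id"] = df["gene_id"].str.upper()
    df = df.assign(is_nonsynonymous=cls.isin(whitelist))
    if "covered_megabases" in df.columns:
        df["covered_megabases"] = pd.to_numeric(df["covered_megabases"])
    elif default_megabases is not None:
        df["covered_megabases"] = float(default_megabases)
    else:
        df["covered_megabases"] = np.nan
    return MutationTable(df)


def load_placeholder_signatures() -> SignatureCollection:
    """The bundled placeholder immune/stroma signature collection.

    Small generic marker lists (T/B/NK cell, macrophage, pooled immune,
    activated stroma) useful for demos and tests; curated
    platform-matched signature lists are drop-in replacements via
    :func:`read_gene_sets`.
    """
    path = Path(__file__).parent / "data" / "placeholder_signatures.gmt"
    return read_gene_sets(path)
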