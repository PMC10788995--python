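"""Reading, validation and alignment of pipeline inputs.

The pipeline consumes four (optionally five) plain-text inputs:

* a gene x sample expression matrix (TSV, one header row of sample IDs),
  assumed already normalized to an FPKM/TPM-like scale — the downstream pair
  indicator is invariant to per-sample monotone transforms, so no within-package
  normalization is performed;
* a clinical table with overall-survival follow-up and categorical covariates;
* an Ensembl-style GTF used only to assign gene biotypes (lncRNA vs coding);
* a gene set of vascular-invasion-related symbols (GRP or single-set GMT);
* optionally a drug x sample IC50 matrix.

Everything is held in small dataclasses wrapping pandas objects; loaders
validate invariants eagerly so failures name the offending gene/sample rather
than surfacing later as numerical errors.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lncpairsig")

#: GTF biotype values collapsed into the package-level "lncRNA" class.  The
#: modern Ensembl annotation uses the single biotype ``lncRNA``; older releases
#: split the class into several legacy labels.  Extend or shrink via the
#: ``lncrna_biotypes`` argument of :func:`load_expression`.
LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "antisense",
        "lincRNA",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
        "bidirectional_promoter_lncRNA",
        "macro_lncRNA",
        "non_coding",
    }
)

VALID_GRADES = ("G1", "G2", "G3", "G4")
VALID_STAGES = ("I", "II", "III", "IV")
VALID_SEX = ("male", "female")
VALID_SUBTYPES = ("C1", "C2", "C3", "C4", "C5", "C6")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, negatives, ...)."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or out of range."""


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a basic stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path!r} must contain a YAML mapping")
    return cfg


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``ENSG...{.N}``) if present."""
    return re.sub(r"\.\d+$", "", gene_id)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundance table with gene biotypes.

    Parameters
    ----------
    values
        DataFrame of abundances, genes in rows, samples in columns.
    biotype
        Per-gene label in {"lncRNA", "protein_coding", "other", "unknown"},
        indexed like ``values``.
    group
        Per-sample label in {"tumor", "normal"}, indexed by sample ID.
    """

    values: pd.DataFrame
    biotype: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        self.biotype = self.biotype.reindex(self.values.index).fillna("unknown")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValidationError(f"samples without tumor/normal group: {missing}")
        bad = set(self.group.unique()) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"invalid sample group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def tumor_samples(self) -> list[str]:
        return self.group.index[self.group == "tumor"].tolist()

    @property
    def normal_samples(self) -> list[str]:
        return self.group.index[self.group == "normal"].tolist()

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.biotype.loc[list(gene_ids)], self.group
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.biotype, self.group.loc[list(sample_ids)]
        )

    def lncrnas(self) -> "ExpressionMatrix":
        """Restrict to genes annotated as lncRNA."""
        keep = self.biotype.index[self.biotype == "lncRNA"].tolist()
        return self.subset_genes(keep)

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class ClinicalTable:
    """Per-sample follow-up and clinical covariates, indexed by sample ID."""

    data: pd.DataFrame

    REQUIRED = ("os_time", "os_event", "age", "sex", "grade", "stage")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate clinical sample IDs: {dups}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if df["os_time"].isna().any() or (df["os_time"] <= 0).any():
            bad = df.index[~(df["os_time"] > 0)].tolist()
            raise ValidationError(f"os_time must be > 0; offending samples: {bad}")
        if not df["os_event"].isin([0, 1]).all():
            bad = df.index[~df["os_event"].isin([0, 1])].tolist()
            raise ValidationError(f"os_event must be 0/1; offending samples: {bad}")
        for col, domain in (
            ("sex", VALID_SEX),
            ("grade", VALID_GRADES),
            ("stage", VALID_STAGES),
        ):
            vals = df[col].dropna()
            bad = set(vals) - set(domain)
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        if "immune_subtype" in df.columns:
            vals = df["immune_subtype"].dropna()
            bad = set(vals) - set(VALID_SUBTYPES)
            if bad:
                raise ValidationError(f"invalid immune_subtype values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def os_time(self) -> pd.Series:
        return self.data["os_time"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.data["os_event"].astype(int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in clinical table: {missing}")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            dups = [m for m in set(self.members) if list(self.members).count(m) > 1]
            raise ValidationError(f"gene set {self.name!r} has duplicate members: {dups}")
        if any(not m or not isinstance(m, str) for m in self.members):
            raise ValidationError(f"gene set {self.name!r} has empty/non-string members")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def read_gtf_biotypes(gtf_path: str | os.PathLike) -> dict[str, str]:
    """Map version-stripped gene IDs to their raw GTF biotype string.

    Only records with feature type ``gene`` are used; both ``gene_biotype``
    (Ensembl) and ``gene_type`` (GENCODE) attribute keys are accepted.
    """
    biotypes: dict[str, str] = {}
    for feat in gffutils.DataIterator(str(gtf_path)):
        if feat.featuretype != "gene":
            continue
        attrs = feat.attributes
        gene_id = (attrs.get("gene_id") or [None])[0]
        if gene_id is None:
            continue
        raw = (attrs.get("gene_biotype") or attrs.get("gene_type") or [None])[0]
        if raw is not None:
            biotypes[strip_gene_version(gene_id)] = raw
    return biotypes


def classify_biotype(raw: str | None, lncrna_biotypes: frozenset[str] = LNCRNA_BIOTYPES) -> str:
    if raw is None:
        return "unknown"
    if raw in lncrna_biotypes:
        return "lncRNA"
    if raw == "protein_coding":
        return "protein_coding"
    return "other"


def _read_matrix_tsv(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2:
        raise ParseError(
            f"{kind} file {path!r}: malformed header at line 1 "
            f"(expected tab-separated sample IDs, got {header!r})"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_expression(
    path: str | os.PathLike,
    gtf_path: str | os.PathLike,
    normal_samples: Iterable[str] = (),
    lncrna_biotypes: frozenset[str] = LNCRNA_BIOTYPES,
) -> ExpressionMatrix:
    """Load an expression TSV and annotate gene biotypes from a GTF.

    Gene-ID version suffixes are stripped on both sides before joining, so
    ``ENSG00000100001.5`` matches a GTF record for ``ENSG00000100001``.  Genes
    absent from the GTF get biotype ``"unknown"`` (logged, not fatal).  Samples
    listed in ``normal_samples`` are labelled ``normal``; all others ``tumor``.
    """
    df = _read_matrix_tsv(path, "expression")
    gtf_map = read_gtf_biotypes(gtf_path)
    raw = [gtf_map.get(strip_gene_version(g)) for g in df.index]
    biotype = pd.Series(
        [classify_biotype(r, lncrna_biotypes) for r in raw], index=df.index, dtype=object
    )
    n_unknown = int((biotype == "unknown").sum())
    if n_unknown:
        logger.warning(
            "%d/%d genes absent from GTF %s; biotype set to 'unknown'",
            n_unknown,
            len(df),
            gtf_path,
        )
    normal = set(normal_samples)
    group = pd.Series(
        ["normal" if s in normal else "tumor" for s in df.columns],
        index=df.columns,
        dtype=object,
    )
    return ExpressionMatrix(df, biotype, group)


def load_clinical(path: str | os.PathLike) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"clinical file {path!r}: missing 'sample_id' column in header")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def load_geneset(path: str | os.PathLike) -> GeneSet:
    """Read a gene set from a GRP (one symbol per line) or single-set GMT file."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"gene set file {path!r} is empty")
    if "\t" in lines[0]:
        if len(lines) > 1:
            raise ParseError(f"GMT file {path!r} contains more than one gene set")
        fields = lines[0].split("\t")
        name, members = fields[0], tuple(m for m in fields[2:] if m)
        return GeneSet(name, members)
    name = os.path.splitext(os.path.basename(str(path)))[0]
    return GeneSet(name, tuple(lines))


def load_ic50(path: str | os.PathLike) -> pd.DataFrame:
    """Load a drug x sample IC50 matrix (values may be any real scale)."""
    df = _read_matrix_tsv(path, "IC50")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate drug names in IC50 matrix: {dups}")
    return df


def align_cohort(
    expr: ExpressionMatrix, clin: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to shared tumor samples, in expression order.

    Normal samples (used only by the tumor-vs-normal screen) are dropped here;
    survival modelling concerns tumors only.
    """
    tumor = expr.tumor_samples
    clin_ids = set(clin.sample_ids)
    shared = [s for s in tumor if s in clin_ids]
    if not shared:
        raise ValidationError("no shared tumor samples between expression and clinical table")
    n_drop_expr = len(expr.sample_ids) - len(shared)
    n_drop_clin = len(clin.sample_ids) - len(shared)
    if n_drop_expr or n_drop_clin:
        logger.info(
            "align_cohort: kept %d shared tumor samples (dropped %d expression, %d clinical)",
            len(shared),
            n_drop_expr,
            n_drop_clin,
        )
    return expr.subset_samples(shared), clin.subset(shared)
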