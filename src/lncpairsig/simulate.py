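"""Synthetic HCC-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, one layer per pipeline stage:

* a per-sample latent *vascular-invasion activity* ``v ~ N(0, 1)``;
* vascular-invasion gene-set members and "linked" lncRNAs load on ``v`` with a
  configurable loading on the log2 scale, so Pearson correlation on logs
  approximates the planted loading (expression is exponentiated afterwards,
  giving log-normal, strictly positive abundances);
* a subset of linked lncRNAs receives an additive tumor-only log2 fold change
  (the planted DElncRNAs);
* overall survival of tumor samples is exponential with hazard
  ``h0 * exp(sum_p beta_p * x_p)`` where ``x_p`` is the 0/1 indicator of a
  planted lncRNA pair, censored by an independent exponential whose rate is
  solved analytically to hit a target censoring fraction;
* categorical clinical covariates and a drug x sample IC50 matrix in which half
  of the drugs depend monotonically on the true log risk.

Defaults mirror the real cohort the pipeline targets: 365 tumor and 50 normal
samples, 14 planted DElncRNAs, and a planted 5-pair signature re-using lncRNAs
across pairs with log-hazard coefficients 0.3776, -0.3176, -0.3402, -0.3572,
0.4547.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .io import ClinicalTable, ConfigError, ExpressionMatrix, GeneSet

__all__ = ["SimulationConfig", "SimulatedCohort", "GroundTruth", "simulate_cohort", "write_cohort"]

#: Planted signature reproducing the published 5-pair topology: one lncRNA
#: appears in three pairs and another in two, with the published coefficients.
DEFAULT_SIGNATURE_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("LNC0001", "LNC0002", 0.3776),
    ("LNC0003", "LNC0004", -0.3176),
    ("LNC0003", "LNC0005", -0.3402),
    ("LNC0003", "LNC0006", -0.3572),
    ("LNC0002", "LNC0007", 0.4547),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_tumor: int = 365
    n_normal: int = 50
    n_lnc: int = 500
    n_coding: int = 200
    n_geneset: int = 50
    factor_loading: float = 0.7
    n_linked_lnc: int = 97
    n_de_lnc: int = 14
    de_log2fc: float = 3.0
    sigma_noise: float = 1.0
    signature_pairs: tuple[tuple[str, str, float], ...] = DEFAULT_SIGNATURE_PAIRS
    baseline_hazard: float = 1.0e-3  # per day
    censor_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_lnc": self.n_lnc,
            "n_coding": self.n_coding,
            "n_geneset": self.n_geneset,
            "n_linked_lnc": self.n_linked_lnc,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_de_lnc < 0:
            raise ConfigError("n_de_lnc must be >= 0")
        if self.n_linked_lnc > self.n_lnc:
            raise ConfigError("n_linked_lnc cannot exceed n_lnc")
        if self.n_de_lnc > self.n_linked_lnc:
            raise ConfigError("n_de_lnc cannot exceed n_linked_lnc")
        if self.n_geneset > self.n_coding:
            raise ConfigError("n_geneset cannot exceed n_coding")
        if not 0.0 <= self.factor_loading <= 1.0:
            raise ConfigError("factor_loading must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.sigma_noise <= 0:
            raise ConfigError("sigma_noise must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        lnc_ids = set(self.lnc_ids)
        for a, b, _ in self.signature_pairs:
            for g in (a, b):
                if g not in lnc_ids:
                    raise ConfigError(f"signature pair references unknown lncRNA {g!r}")
            if a == b:
                raise ConfigError(f"signature pair ({a}, {b}) is degenerate")

    @property
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lnc)]

    @property
    def coding_ids(self) -> list[str]:
        return [f"PCG{i + 1:04d}" for i in range(self.n_coding)]

    @property
    def linked_lnc_ids(self) -> list[str]:
        return self.lnc_ids[: self.n_linked_lnc]

    @property
    def de_lnc_ids(self) -> list[str]:
        return self.lnc_ids[: self.n_de_lnc]

    @property
    def geneset_ids(self) -> list[str]:
        return self.coding_ids[: self.n_geneset]


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for benchmarking recovery."""

    linked_lnc: list[str]
    de_lnc: list[str]
    signature_pairs: list[tuple[str, str, float]]
    true_log_risk: pd.Series  # per tumor sample, sum(beta * x)
    censoring_hazard: float
    sensitive_drugs: list[str]


@dataclass
class SimulatedCohort:
    expr: ExpressionMatrix
    clinical: ClinicalTable
    geneset: GeneSet
    ic50: pd.DataFrame
    truth: GroundTruth


def _solve_censoring_hazard(hazards: np.ndarray, censor_rate: float) -> float:
    """Rate of the independent exponential censor hitting ``censor_rate``.

    Under exponential event/censoring times, sample ``s`` is censored with
    probability ``c / (c + h_s)``; the mean over samples is monotone in ``c``,
    so the target rate has a unique root.
    """
    if censor_rate == 0.0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - censor_rate

    hi = float(hazards.max()) * censor_rate / (1 - censor_rate) + 1e-12
    while frac(hi) < 0:
        hi *= 2.0
    return brentq(frac, 0.0, hi, xtol=1e-14, rtol=1e-12)


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate one cohort; fully reproducible from ``config.seed``.

    Keyword overrides are applied on top of ``config`` (or the defaults), e.g.
    ``simulate_cohort(n_tumor=400, seed=3)``.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_samples = cfg.n_tumor + cfg.n_normal
    tumor_ids = [f"T{i + 1:04d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(cfg.n_normal)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([True] * cfg.n_tumor + [False] * cfg.n_normal)

    v = rng.standard_normal(n_samples)  # latent vascular-invasion activity
    f = cfg.factor_loading
    resid = float(np.sqrt(max(1.0 - f * f, 0.0)))

    gene_ids = cfg.lnc_ids + cfg.coding_ids
    log2expr = np.empty((len(gene_ids), n_samples))

    # Baseline log2 means.  Planted DElncRNAs share one mean so that their
    # pairwise indicators stay balanced (validity filter keeps them).
    mu = np.empty(len(gene_ids))
    mu[: cfg.n_lnc] = rng.uniform(2.0, 8.0, cfg.n_lnc)
    mu[: cfg.n_de_lnc] = 5.0
    mu[cfg.n_de_lnc : cfg.n_linked_lnc] = rng.normal(5.0, 1.0, cfg.n_linked_lnc - cfg.n_de_lnc)
    mu[cfg.n_lnc :] = rng.uniform(2.0, 8.0, cfg.n_coding)

    noise = rng.standard_normal((len(gene_ids), n_samples)) * cfg.sigma_noise
    loaded = np.zeros(len(gene_ids), dtype=bool)
    loaded[: cfg.n_linked_lnc] = True  # linked lncRNAs
    loaded[cfg.n_lnc : cfg.n_lnc + cfg.n_geneset] = True  # gene-set members
    log2expr[:] = mu[:, None] + noise
    log2expr[loaded] = mu[loaded, None] + f * v[None, :] + resid * noise[loaded]
    # tumor-only differential expression of the planted DElncRNAs
    log2expr[: cfg.n_de_lnc, is_tumor] += cfg.de_log2fc

    values = pd.DataFrame(np.exp2(log2expr), index=gene_ids, columns=sample_ids)
    biotype = pd.Series(
        ["lncRNA"] * cfg.n_lnc + ["protein_coding"] * cfg.n_coding, index=gene_ids, dtype=object
    )
    group = pd.Series(np.where(is_tumor, "tumor", "normal"), index=sample_ids, dtype=object)
    expr = ExpressionMatrix(values, biotype, group)

    # --- survival of tumor samples, hazard driven by planted pair indicators
    tumor_values = values[tumor_ids]
    log_risk = np.zeros(cfg.n_tumor)
    for a, b, beta in cfg.signature_pairs:
        x = (tumor_values.loc[a].to_numpy() > tumor_values.loc[b].to_numpy()).astype(float)
        log_risk += beta * x
    hazards = cfg.baseline_hazard * np.exp(log_risk)
    event_time = rng.exponential(1.0 / hazards)
    c_hazard = _solve_censoring_hazard(hazards, cfg.censor_rate)
    if c_hazard > 0:
        censor_time = rng.exponential(1.0 / c_hazard, cfg.n_tumor)
    else:
        censor_time = np.full(cfg.n_tumor, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    age = np.clip(np.round(rng.normal(61.0, 11.0, cfg.n_tumor)), 18, 90).astype(int)
    sex = rng.choice(["male", "female"], cfg.n_tumor, p=[0.68, 0.32])
    grade = rng.choice(["G1", "G2", "G3", "G4"], cfg.n_tumor, p=[0.15, 0.45, 0.30, 0.10])
    stage = rng.choice(["I", "II", "III", "IV"], cfg.n_tumor, p=[0.48, 0.24, 0.22, 0.06])
    # C5/C6 absent, as in the cohort the generator emulates
    subtype = rng.choice(["C1", "C2", "C3", "C4"], cfg.n_tumor, p=[0.25, 0.35, 0.25, 0.15])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "sex": sex,
                "grade": grade,
                "stage": stage,
                "immune_subtype": subtype,
            },
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    geneset = GeneSet("vascular_invasion", tuple(cfg.geneset_ids))

    # --- IC50 matrix: first half of the drugs monotone in the true log risk
    drug_names = [
        "sorafenib",
        "nilotinib",
        "rapamycin",
        "cisplatin",
        "mitomycin_c",
        "pd0325901",
        "erlotinib",
        "gemcitabine",
        "paclitaxel",
        "doxorubicin",
        "vinblastine",
        "etoposide",
        "axitinib",
        "lapatinib",
    ]
    sensitive = drug_names[: len(drug_names) // 2]
    ic50 = np.empty((len(drug_names), cfg.n_tumor))
    sd_risk = float(np.std(log_risk)) or 1.0
    for i, drug in enumerate(drug_names):
        base = rng.uniform(1.0, 5.0)
        ic50[i] = base + rng.normal(0.0, 0.5, cfg.n_tumor)
        if drug in sensitive:
            ic50[i] += 1.0 * (log_risk - log_risk.mean()) / sd_risk
    ic50_df = pd.DataFrame(ic50, index=drug_names, columns=tumor_ids)

    truth = GroundTruth(
        linked_lnc=cfg.linked_lnc_ids,
        de_lnc=cfg.de_lnc_ids,
        signature_pairs=[tuple(p) for p in cfg.signature_pairs],
        true_log_risk=pd.Series(log_risk, index=tumor_ids, name="log_risk"),
        censoring_hazard=c_hazard,
        sensitive_drugs=sensitive,
    )
    return SimulatedCohort(expr, clinical, geneset, ic50_df, truth)


def _write_gtf(cohort: SimulatedCohort, path: str | os.PathLike) -> None:
    """Minimal GTF with one ``gene`` record per simulated gene."""
    with open(path, "w") as fh:
        pos = 1000
        for gene, bt in cohort.expr.biotype.items():
            raw = "lncRNA" if bt == "lncRNA" else "protein_coding"
            attrs = f'gene_id "{gene}"; gene_name "{gene}"; gene_biotype "{raw}";'
            fh.write(f"chr1\tsim\tgene\t{pos}\t{pos + 999}\t.\t+\t.\t{attrs}\n")
            pos += 2000


def write_cohort(cohort: SimulatedCohort, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a cohort in the loader formats plus a ground-truth YAML."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "clinical": os.path.join(outdir, "clinical.tsv"),
        "geneset": os.path.join(outdir, "geneset.grp"),
        "ic50": os.path.join(outdir, "ic50.tsv"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "truth": os.path.join(outdir, "truth.yaml"),
    }
    cohort.expr.to_tsv(paths["expression"])
    cohort.clinical.to_tsv(paths["clinical"])
    with open(paths["geneset"], "w") as fh:
        fh.write("\n".join(cohort.geneset.members) + "\n")
    out = cohort.ic50.copy()
    out.index.name = "drug"
    out.to_csv(paths["ic50"], sep="\t")
    _write_gtf(cohort, paths["gtf"])
    truth = {
        "linked_lnc": list(cohort.truth.linked_lnc),
        "de_lnc": list(cohort.truth.de_lnc),
        "signature_pairs": [
            {"lnc_a": a, "lnc_b": b, "beta": float(beta)}
            for a, b, beta in cohort.truth.signature_pairs
        ],
        "censoring_hazard": float(cohort.truth.censoring_hazard),
        "sensitive_drugs": list(cohort.truth.sensitive_drugs),
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return paths
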