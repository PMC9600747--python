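"""Synthetic sorted-cell and bulk-tumor data with known ground truth.

The generator emulates the data structure the discovery pipeline consumes:

* *reference profiles* — several myeloid cell types profiled in replicate on
  a log2 expression scale, each type carrying a planted block of signature
  genes elevated over baseline, with replicate noise and additive/
  multiplicative study-batch effects;
* *bulk cohorts* — tumors built as noisy convex mixtures (in linear space)
  of the cell-type mean profiles, with a known fraction of the target cell
  type per tumor and an ordinal grade derived from terciles of that
  fraction;
* *survival* — proportional-hazards event times driven by the standardized
  target-cell fraction, with uniform administrative censoring.

All randomness derives from one integer seed through a hierarchical
``SeedSequence``; each generation stage uses its own child stream so stages
can be regenerated independently and deterministically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

TARGET_CELL_TYPE = "ercDC"

# child-stream indices of the hierarchical seed
_STREAM_REFERENCE = 0
_STREAM_BULK = 1
_STREAM_SURVIVAL = 2


class ConfigurationError(ValueError):
    """A SimConfig field violates its documented bound."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults are chosen to resemble sorted-cell microarray experiments and a
    TCGA-sized tumor cohort: log2-scale expression around 7 with replicate
    noise SD 0.5, cell-type markers at a 4-fold (2.0 log2) effect, three
    study batches with modest location/scale effects, 400 tumors mixed from
    a flat Dirichlet, and a hazard ratio of 2 per SD of target-cell fraction
    with administrative censoring yielding roughly half censored subjects.
    """

    n_genes: int = 2000
    n_celltypes: int = 4
    n_replicates_per_type: int = 12
    n_signature_genes_per_type: int = 30
    signature_effect: float = 2.0
    replicate_sd: float = 0.5
    n_batches: int = 3
    batch_location_sd: float = 0.3
    batch_scale_sd: float = 0.1
    n_tumors: int = 400
    mixing_concentration: tuple[float, ...] | None = None
    bulk_noise_sd: float = 0.25
    hazard_log_hr: float = float(np.log(2.0))
    baseline_hazard: float = 0.1
    censor_time_max: float = 20.0
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5

    def validate(self) -> None:
        for name in ("n_genes", "n_celltypes", "n_replicates_per_type",
                     "n_signature_genes_per_type", "n_batches", "n_tumors"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("replicate_sd", "batch_location_sd", "batch_scale_sd",
                     "bulk_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        n_sig = self.n_signature_genes_per_type * self.n_celltypes
        if not 0 < n_sig <= self.n_genes:
            raise ConfigurationError(
                f"n_signature_genes_per_type * n_celltypes = {n_sig} must be in "
                f"(0, n_genes={self.n_genes}]"
            )
        if self.mixing_concentration is not None:
            conc = np.asarray(self.mixing_concentration, dtype=float)
            if conc.shape != (self.n_celltypes,):
                raise ConfigurationError(
                    f"mixing_concentration must have length n_celltypes="
                    f"{self.n_celltypes}, got {conc.shape}"
                )
            if not (conc > 0).all():
                raise ConfigurationError("mixing_concentration entries must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(
                f"baseline_hazard must be > 0, got {self.baseline_hazard}"
            )
        if self.censor_time_max <= 0:
            raise ConfigurationError("censor_time_max must be > 0")

    @property
    def cell_types(self) -> list[str]:
        return [TARGET_CELL_TYPE] + [f"myeloid_{k}" for k in range(2, self.n_celltypes + 1)]

    @property
    def concentration(self) -> np.ndarray:
        if self.mixing_concentration is None:
            return np.ones(self.n_celltypes)
        return np.asarray(self.mixing_concentration, dtype=float)

    def stream(self, index: int) -> np.random.Generator:
        """Child RNG stream ``index`` of the hierarchical seed."""
        child = np.random.SeedSequence(self.seed).spawn(max(index + 1, 3))[index]
        return np.random.default_rng(child)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic data set."""

    signature_gene_assignment: dict[str, str]
    signature_direction: dict[str, int]  # gene -> +1 (up) or -1 (down)
    cell_types: list[str]
    mean_profiles: pd.DataFrame  # genes x cell types, log2
    mixing_fractions: pd.DataFrame | None = None  # tumors x cell types
    true_grade: pd.Series | None = None  # ordinal {1,2,3} per tumor
    true_log_hr: float | None = None
    target: str = TARGET_CELL_TYPE

    def to_json_dict(self) -> dict:
        out: dict = {
            "signature_gene_assignment": self.signature_gene_assignment,
            "signature_direction": self.signature_direction,
            "cell_types": self.cell_types,
            "mean_profiles": self.mean_profiles.round(10).to_dict(orient="index"),
            "target": self.target,
            "true_log_hr": self.true_log_hr,
        }
        if self.mixing_fractions is not None:
            out["mixing_fractions"] = self.mixing_fractions.round(12).to_dict(orient="index")
        if self.true_grade is not None:
            out["true_grade"] = {k: int(v) for k, v in self.true_grade.items()}
        return out


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_reference_profiles(cfg: SimConfig):
    """Simulate sorted-cell reference transcriptomes.

    Returns ``(expr, annotation, truth)`` where ``expr`` is genes x samples
    (log2), ``annotation`` carries ``cell_type`` and ``study_batch`` per
    sample, and ``truth`` records the planted signature assignment and the
    noiseless cell-type mean profiles.
    """
    cfg.validate()
    rng = cfg.stream(_STREAM_REFERENCE)
    genes = _gene_ids(cfg.n_genes)
    types = cfg.cell_types
    n_sig = cfg.n_signature_genes_per_type

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    means = np.tile(baseline[:, None], (1, cfg.n_celltypes))
    assignment: dict[str, str] = {}
    direction: dict[str, int] = {}
    # bidirectional signatures (~2:1 up:down, as cell-type panels typically
    # are): a one-directional panel would make the reference-regression slope
    # collinear with its intercept and carry no mixing signal
    n_up = int(np.ceil(2 * n_sig / 3))
    for k, ct in enumerate(types):
        block = range(k * n_sig, (k + 1) * n_sig)
        for pos, gi in enumerate(block):
            sign = 1 if pos < n_up else -1
            means[gi, k] += sign * cfg.signature_effect
            assignment[genes[gi]] = ct
            direction[genes[gi]] = sign

    n_samples = cfg.n_celltypes * cfg.n_replicates_per_type
    sample_ids, cell_type_col = [], []
    for ct in types:
        for r in range(1, cfg.n_replicates_per_type + 1):
            sample_ids.append(f"{ct}_r{r:02d}")
            cell_type_col.append(ct)
    batches = [f"batch{(j % cfg.n_batches) + 1}" for j in range(n_samples)]

    batch_names = [f"batch{b + 1}" for b in range(cfg.n_batches)]
    batch_shift = {b: rng.normal(0.0, cfg.batch_location_sd, size=cfg.n_genes)
                   for b in batch_names}
    batch_scale = {b: float(np.exp(rng.normal(0.0, cfg.batch_scale_sd)))
                   for b in batch_names}

    values = np.empty((cfg.n_genes, n_samples))
    for j, (ct, b) in enumerate(zip(cell_type_col, batches)):
        k = types.index(ct)
        noise = rng.normal(0.0, cfg.replicate_sd, size=cfg.n_genes)
        values[:, j] = means[:, k] + batch_shift[b] + batch_scale[b] * noise

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    ann = pd.DataFrame(
        {"cell_type": cell_type_col, "study_batch": batches},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        signature_gene_assignment=assignment,
        signature_direction=direction,
        cell_types=types,
        mean_profiles=pd.DataFrame(means, index=expr.index, columns=types),
    )
    return expr, ann, truth


def generate_bulk_cohort(cfg: SimConfig, reference_truth: SyntheticTruth):
    """Simulate a bulk tumor cohort as convex mixtures of cell-type profiles.

    Mixing happens in linear space (cell abundances add linearly), then the
    column is re-logged and Gaussian log2 noise added.  Grade is the tercile
    of the target-cell fraction mapped to {1, 2, 3}.
    """
    cfg.validate()
    profiles = reference_truth.mean_profiles
    if list(profiles.columns) != cfg.cell_types:
        raise ValueError(
            "reference truth cell types do not match config "
            f"({list(profiles.columns)} vs {cfg.cell_types})"
        )
    if len(profiles.index) != cfg.n_genes:
        raise ValueError(
            f"gene universe mismatch: truth has {len(profiles.index)} genes, "
            f"config expects {cfg.n_genes}"
        )
    rng = cfg.stream(_STREAM_BULK)
    w = rng.dirichlet(cfg.concentration, size=cfg.n_tumors)  # tumors x types
    linear = np.power(2.0, profiles.to_numpy())  # genes x types
    mixed = linear @ w.T  # genes x tumors
    noise = rng.normal(0.0, cfg.bulk_noise_sd, size=mixed.shape)
    values = np.log2(mixed) + noise

    tumor_ids = [f"tumor_{i:04d}" for i in range(1, cfg.n_tumors + 1)]
    expr = pd.DataFrame(values, index=profiles.index.copy(), columns=tumor_ids)

    target_idx = cfg.cell_types.index(reference_truth.target)
    frac = w[:, target_idx]
    grade = np.searchsorted(np.quantile(frac, [1 / 3, 2 / 3]), frac, side="right") + 1
    grade = pd.Series(grade, index=tumor_ids, name="grade")

    mixing = pd.DataFrame(w, index=tumor_ids, columns=cfg.cell_types)
    truth = SyntheticTruth(
        signature_gene_assignment=reference_truth.signature_gene_assignment,
        signature_direction=reference_truth.signature_direction,
        cell_types=cfg.cell_types,
        mean_profiles=profiles,
        mixing_fractions=mixing,
        true_grade=grade,
        true_log_hr=cfg.hazard_log_hr,
        target=reference_truth.target,
    )
    ann = pd.DataFrame({"grade": grade}, index=pd.Index(tumor_ids, name="sample_id"))
    return expr, ann, truth


def generate_survival(cfg: SimConfig, truth: SyntheticTruth,
                      dichotomize_at_median: bool = False) -> pd.DataFrame:
    """Simulate proportional-hazards survival driven by the target fraction.

    Event times are Exponential with rate
    ``baseline_hazard * exp(hazard_log_hr * z)`` where ``z`` is the
    standardized target-cell fraction; censoring is Uniform(0,
    censor_time_max).  All returned times are strictly positive.

    With ``dichotomize_at_median=True`` the hazard instead contrasts the
    high/low halves of the fraction: ``z`` is the 0/1 above-median
    indicator, so ``exp(hazard_log_hr)`` is exactly the hazard ratio
    between the two groups (the design used for end-to-end
    score->cutpoint->Cox recovery checks).
    """
    cfg.validate()
    if truth.mixing_fractions is None:
        raise ValueError("truth has no mixing_fractions; generate the bulk cohort first")
    rng = cfg.stream(_STREAM_SURVIVAL)
    frac = truth.mixing_fractions[truth.target].to_numpy()
    if dichotomize_at_median:
        z = (frac > np.median(frac)).astype(float)
    else:
        z = (frac - frac.mean()) / frac.std(ddof=1)
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_log_hr * z)
    event_time = rng.exponential(1.0 / rate)
    if np.isfinite(cfg.censor_time_max):
        censor_time = rng.uniform(0.0, cfg.censor_time_max, size=len(frac))
    else:
        censor_time = np.full(len(frac), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)  # follow-up must be > 0

    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "true_fraction": frac,
            "grade": truth.true_grade.to_numpy() if truth.true_grade is not None else np.nan,
        },
        index=pd.Index(truth.mixing_fractions.index, name="subject_id"),
    )


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    if d["mixing_concentration"] is not None:
        d["mixing_concentration"] = list(d["mixing_concentration"])
    return d
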