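"""Synthetic multi-study treatment-mean databases.

The generator draws data with exactly the statistical structure the mixed
model assumes: a shared study-level intercept deviation s_i ~ N(0, tau^2)
and residuals e_ij ~ N(0, sigma^2 / w_ij) whose variance shrinks with the
number of animals w_ij behind each treatment mean.  Predictors are uniform
over their observed literature ranges, which maximises design spread for
slope recovery and keeps the convention explicit.

Two calibration presets ship with the package: the urinary and fecal
K-intake equations (slope 0.65 and 0.126 g excreted per g K ingested over
K-intake ranges of roughly 105-686 and 105-583 g/d), with between-study SD
30 and 8 g/d and unit-weight residual SD 25 and 10 g/d respectively, 17
studies of 2-4 treatment means weighted by 4-12 animals.  These are the
standing study conditions for every recovery simulation in the package.

Randomness: one root seed spawns independent per-study streams
(``numpy.random.SeedSequence``), so a study's draws do not depend on how
many other studies exist — convenient for fold-level reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .database import StudyDatabase, TreatmentMeanRecord

__all__ = [
    "SyntheticConfig",
    "MultivariableConfig",
    "URINARY_K_INTAKE",
    "FECAL_K_INTAKE",
    "generate",
    "generate_multivariable",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative counterpart of the mixed model, single predictor.

    Defaults are the urinary K-intake calibration (see module docstring).
    ``outlier_spec=(count, multiplier)`` plants extreme responses by
    multiplying randomly chosen records, mimicking the implausible excretion
    values screened out of real literature data.
    """

    n_studies: int = 17
    records_per_study: tuple[int, int] = (2, 4)
    beta0: float = 1.08          # g/d
    beta1: float = 0.65          # g response per predictor unit
    tau: float = 30.0            # between-study SD, g/d
    sigma: float = 25.0          # unit-weight residual SD, g/d
    predictor_name: str = "k_intake"
    response_name: str = "k_ur"
    predictor_range: tuple[float, float] = (105.3, 686.0)
    weight_range: tuple[int, int] = (4, 12)
    seed: int = 0
    outlier_spec: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2")
        if self.records_per_study[0] < 1 or self.records_per_study[0] > self.records_per_study[1]:
            raise ValueError(f"invalid records_per_study {self.records_per_study}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.predictor_range[0] >= self.predictor_range[1]:
            raise ValueError(f"invalid predictor_range {self.predictor_range}")
        if self.weight_range[0] < 1 or self.weight_range[0] > self.weight_range[1]:
            raise ValueError(f"invalid weight_range {self.weight_range}")


URINARY_K_INTAKE = SyntheticConfig()
FECAL_K_INTAKE = SyntheticConfig(
    beta0=6.93,
    beta1=0.126,
    tau=8.0,
    sigma=10.0,
    response_name="k_fa",
    predictor_range=(105.3, 583.0),
)


def generate(config: SyntheticConfig) -> StudyDatabase:
    """Draw one multi-study database; bit-identical for identical configs.

    Per study i: s_i ~ N(0, tau^2); per record j: x_ij ~ U(predictor range),
    w_ij ~ UniformInteger(weight range), e_ij ~ N(0, sigma^2 / w_ij),
    y_ij = beta0 + beta1 x_ij + s_i + e_ij.  Negative responses (possible
    under statistically legitimate but physiologically extreme parameters)
    are kept with a warning: the generator is statistical, not physiological.
    """
    root = np.random.SeedSequence(config.seed)
    study_seeds = root.spawn(config.n_studies + 1)  # last stream reserved for outlier placement
    records: list[TreatmentMeanRecord] = []
    lo, hi = config.records_per_study
    wlo, whi = config.weight_range
    for i in range(config.n_studies):
        rng = np.random.default_rng(study_seeds[i])
        study_id = f"S{i + 1:02d}"
        s_i = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
        n_rec = int(rng.integers(lo, hi + 1))
        for j in range(n_rec):
            x = float(rng.uniform(*config.predictor_range))
            w = int(rng.integers(wlo, whi + 1))
            e = float(rng.normal(0.0, config.sigma / np.sqrt(w)))
            y = config.beta0 + config.beta1 * x + s_i + e
            records.append(
                TreatmentMeanRecord(
                    record_id=f"{study_id}_R{j + 1}",
                    study_id=study_id,
                    n_obs=w,
                    **{config.predictor_name: x, config.response_name: y},
                )
            )
    if config.outlier_spec is not None:
        count, mult = config.outlier_spec
        orng = np.random.default_rng(study_seeds[-1])
        chosen = orng.choice(len(records), size=count, replace=False)
        for k in chosen:
            r = records[k]
            records[k] = replace(r, **{config.response_name: r.get(config.response_name) * mult})
    if any(r.get(config.response_name) <= 0 for r in records):
        warnings.warn("generator produced non-positive responses; parameters are physiologically implausible")
    return StudyDatabase(
        records=tuple(records),
        response_name=config.response_name,
        provenance=f"synthetic: seed={config.seed} beta=({config.beta0},{config.beta1}) "
        f"tau={config.tau} sigma={config.sigma} x={config.predictor_name}",
    )


@dataclass(frozen=True)
class MultivariableConfig:
    """Jointly generated predictors via a Gaussian copula.

    ``predictor_ranges`` maps predictor names to (min, max); marginals are
    uniform over those ranges, with cross-dependence induced by
    ``correlations`` (a positive semi-definite matrix in the order of
    ``predictor_ranges``).  When both dmi and dietary_k are generated and
    k_intake is requested, k_intake is SET to dmi x dietary_k x 10 so every
    record satisfies the database consistency identity; the response is
    driven by ``driving_predictor`` alone.
    """

    predictor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"dmi": (4.4, 27.6), "dietary_k": (0.79, 2.73)}
    )
    correlations: np.ndarray | None = None
    driving_predictor: str = "k_intake"
    derive_k_intake: bool = True
    n_studies: int = 17
    records_per_study: tuple[int, int] = (2, 4)
    beta0: float = 1.08
    beta1: float = 0.65
    tau: float = 30.0
    sigma: float = 25.0
    response_name: str = "k_ur"
    weight_range: tuple[int, int] = (4, 12)
    seed: int = 0
    outlier_spec: tuple[int, float] | None = None


def generate_multivariable(config: MultivariableConfig) -> StudyDatabase:
    """Multi-predictor databases respecting the K-intake consistency identity."""
    names = list(config.predictor_ranges)
    k = len(names)
    if config.correlations is not None:
        C = np.asarray(config.correlations, dtype=float)
        if C.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        C = np.clip(C, -1, 1)
    else:
        C = np.eye(k)
    with_k_intake = config.derive_k_intake and "dmi" in names and "dietary_k" in names
    root = np.random.SeedSequence(config.seed)
    study_seeds = root.spawn(config.n_studies + 1)
    records: list[TreatmentMeanRecord] = []
    lo, hi = config.records_per_study
    wlo, whi = config.weight_range
    for i in range(config.n_studies):
        rng = np.random.default_rng(study_seeds[i])
        study_id = f"S{i + 1:02d}"
        s_i = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
        n_rec = int(rng.integers(lo, hi + 1))
        z = rng.multivariate_normal(np.zeros(k), C, size=n_rec, method="svd")
        u = stats.norm.cdf(z)  # Gaussian copula -> uniform marginals
        for j in range(n_rec):
            values: dict[str, float] = {}
            for m, name in enumerate(names):
                a, b = config.predictor_ranges[name]
                values[name] = a + (b - a) * float(u[j, m])
            if with_k_intake:
                values["k_intake"] = values["dmi"] * values["dietary_k"] * 10.0
            if config.driving_predictor not in values:
                raise ValueError(f"driving predictor {config.driving_predictor!r} not generated")
            w = int(rng.integers(wlo, whi + 1))
            e = float(rng.normal(0.0, config.sigma / np.sqrt(w)))
            y = config.beta0 + config.beta1 * values[config.driving_predictor] + s_i + e
            records.append(
                TreatmentMeanRecord(
                    record_id=f"{study_id}_R{j + 1}",
                    study_id=study_id,
                    n_obs=w,
                    k_intake_derived=with_k_intake,
                    **{config.response_name: y},
                    **values,
                )
            )
    if config.outlier_spec is not None:
        count, mult = config.outlier_spec
        orng = np.random.default_rng(study_seeds[-1])
        for k_ in orng.choice(len(records), size=count, replace=False):
            r = records[k_]
            records[k_] = replace(r, **{config.response_name: r.get(config.response_name) * mult})
    return StudyDatabase(
        records=tuple(records),
        response_name=config.response_name,
        provenance=f"synthetic-multivariable: seed={config.seed} predictors={names} "
        f"driver={config.driving_predictor}",
    )
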