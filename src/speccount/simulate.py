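"""Synthetic spectral-count matrices with known ground truth.

The generator emulates the study design: three cancer groups with 4-5
patients each, every patient's digest injected in triplicate, on the order
of 1,000-2,000 detectable proteins. Per-protein expected abundance follows a
long-tailed log-normal law (a few proteins dominate the spectrum counts, as
in real shotgun runs); a designated subset carries group-specific fold
changes. Per-run counts are Poisson around the per-replicate expectation, or
negative-binomial when biological between-patient overdispersion is wanted.
The default per-replicate depth is set so pooled per-patient totals land
near 1,900 spectra, the scale of the study.

What the generator does NOT emulate: peptide-level sampling, shared-peptide
ambiguity, run-to-run retention drift, and detection censoring — so passing
recovery tests demonstrate the statistical machinery, not search-engine
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_model import CountMatrix, SampleInfo
from .pairwise import PairwiseResult

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "CalibrationMetrics",
    "generate",
    "evaluate_calibration",
]

#: pooled per-patient total ~ 3 replicates x 633 ~ 1,900 spectra
DEFAULT_DEPTH = 633.0


@dataclass
class SyntheticConfig:
    """Design and distributional parameters of a synthetic experiment.

    Parameters
    ----------
    n_proteins
        Number of simulated proteins.
    groups
        Mapping of group label to number of patients (default mirrors the
        study: LCNEC 4, SCLC 5, LCC 5).
    replicates_per_patient
        Technical injections per patient, pooled downstream (default 3).
    mu, sigma
        Log-normal parameters of relative protein abundance (dimensionless;
        sigma ~ 1.5 gives the typical few-orders-of-magnitude dynamic range).
    differential_spec
        List of (protein_index, group_label, fold_change): the protein's
        rate in that group is multiplied by the fold change.
    dispersion
        Overdispersion phi; 0 means Poisson counts, phi > 0 draws
        negative-binomial counts with variance m + phi * m^2.
    depth
        Expected total spectra per single replicate run.
    seed
        Seed of the generator; identical seeds give bit-identical output.
    """

    n_proteins: int = 1500
    groups: dict[str, int] = field(
        default_factory=lambda: {"LCNEC": 4, "SCLC": 5, "LCC": 5}
    )
    replicates_per_patient: int = 3
    mu: float = 0.0
    sigma: float = 1.5
    differential_spec: list[tuple[int, str, float]] = field(default_factory=list)
    dispersion: float = 0.0
    depth: float = DEFAULT_DEPTH
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not self.groups or any(k < 1 for k in self.groups.values()):
            raise ValueError("every group needs at least one patient")
        for idx, grp, fold in self.differential_spec:
            if not 0 <= idx < self.n_proteins:
                raise ValueError(f"differential protein index {idx} out of range")
            if grp not in self.groups:
                raise ValueError(f"differential group {grp!r} unknown")
            if fold <= 0:
                raise ValueError(f"fold change must be positive, got {fold}")


@dataclass
class SyntheticTruth:
    """Ground truth: per-group rates, differential flags and fold changes."""

    rates: np.ndarray  # (n_proteins, n_groups) expected counts per replicate
    groups: list[str]
    is_differential: np.ndarray  # bool per protein
    fold_changes: dict[int, tuple[str, float]]


def generate(config: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic count matrix and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(config.mu, config.sigma, config.n_proteins)
    base /= base.sum()  # relative abundance; null expected depth is exact
    group_labels = list(config.groups)
    rates = np.tile((base * config.depth)[:, None], (1, len(group_labels)))
    fold_map: dict[int, tuple[str, float]] = {}
    for idx, grp, fold in config.differential_spec:
        rates[idx, group_labels.index(grp)] *= fold
        fold_map[idx] = (grp, fold)
    is_diff = np.zeros(config.n_proteins, dtype=bool)
    for idx, (_, fold) in fold_map.items():
        is_diff[idx] = fold != 1.0

    samples: list[SampleInfo] = []
    columns: list[np.ndarray] = []
    for gi, grp in enumerate(group_labels):
        lam = rates[:, gi]
        for pat in range(1, config.groups[grp] + 1):
            for rep in range(1, config.replicates_per_patient + 1):
                if config.dispersion > 0:
                    r = 1.0 / config.dispersion
                    counts = rng.negative_binomial(r, r / (r + lam))
                else:
                    counts = rng.poisson(lam)
                columns.append(counts)
                samples.append(
                    SampleInfo(
                        sample_id=f"{grp}_p{pat}_r{rep}",
                        group=grp,
                        patient_id=f"{grp}_p{pat}",
                        replicate=rep,
                    )
                )
    matrix = CountMatrix(
        protein_ids=[f"PROT{i:05d}" for i in range(config.n_proteins)],
        samples=samples,
        counts=np.column_stack(columns).astype(np.int64),
    )
    truth = SyntheticTruth(
        rates=rates,
        groups=group_labels,
        is_differential=is_diff,
        fold_changes=fold_map,
    )
    return matrix, truth


@dataclass(frozen=True)
class CalibrationMetrics:
    """Operating characteristics of a screen against generator ground truth."""

    type_i_error: float | None  # flagged fraction among true nulls
    power: float | None  # flagged fraction among true differentials
    fdp: float | None  # false-discovery proportion among flagged
    n_null: int
    n_differential: int
    n_flagged: int


def evaluate_calibration(
    results: list[PairwiseResult],
    truth: SyntheticTruth,
    alpha: float = 0.05,
) -> CalibrationMetrics:
    """Type-I error, power and false-discovery proportion of a screen.

    A protein counts as flagged when its G-test p-value is below ``alpha``.
    Degenerate strata (no nulls, no differentials, nothing flagged) report
    ``None`` for the corresponding rate.
    """
    idx = {f"PROT{i:05d}": i for i in range(len(truth.is_differential))}
    missing = [r.protein_id for r in results if r.protein_id not in idx]
    if missing or len(results) != len(truth.is_differential):
        raise ValueError("results and truth cover different protein sets")
    flagged = np.zeros(len(truth.is_differential), dtype=bool)
    for r in results:
        flagged[idx[r.protein_id]] = r.p < alpha
    nulls = ~truth.is_differential
    n_null = int(nulls.sum())
    n_diff = int(truth.is_differential.sum())
    n_flagged = int(flagged.sum())
    return CalibrationMetrics(
        type_i_error=float(flagged[nulls].mean()) if n_null else None,
        power=float(flagged[truth.is_differential].mean()) if n_diff else None,
        fdp=float((flagged & nulls).sum() / n_flagged) if n_flagged else None,
        n_null=n_null,
        n_differential=n_diff,
        n_flagged=n_flagged,
    )
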