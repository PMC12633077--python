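"""Synthetic cohorts and microbial communities for the circadian pipeline.

The generators reproduce the statistical structure the analysis assumes,
at the scale of the motivating study design: two groups, six timepoints at
4-hour intervals across 24 h (ZT2 … ZT22), 3–6 subjects per group per
timepoint, each subject measured once.  Host-style measurements follow

    Y(t) = M + A*cos(2*pi*t/tau + phi) + e,  e ~ N(0, sigma^2)

with additive homoscedastic Gaussian noise per feature (the error model
implied by fitting OLS cosinor).  16S-like communities draw, per sample, a
Dirichlet-perturbed composition around time-varying expected proportions
(baseline plus a per-taxon cosine oscillation, renormalized), then
multinomial counts at a lognormal library size.  Every generator is a pure
function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cosinor import DEFAULT_PERIOD_H, InvalidArgumentError, fit_single_cosinor
from .microbiome import RANKS, TaxaTable
from .pipeline import CohortTable

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "GroupTruth",
    "FeatureSpec",
    "SimulationSpec",
    "CommunitySpec",
    "simulate_cohort",
    "simulate_null_cohort",
    "simulate_microbiome",
    "parameter_recovery",
    "circular_mean_h",
]

#: ZT2 … ZT22 — six timepoints at 4-h intervals over the 24-h cycle.
DEFAULT_TIMEPOINTS: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth cosinor parameters for one (feature, group) cell."""

    mesor: float
    amplitude: float
    acrophase_h: float


@dataclass(frozen=True)
class FeatureSpec:
    """One simulated feature: per-group truth plus a noise level.

    ``noise_sd`` defaults to amplitude/4 of the first group — a
    moderate-noise convention (rhythm clearly present but individual
    variation visible) used when no dispersion is specified.
    """

    name: str
    groups: dict[str, GroupTruth]
    noise_sd: float | None = None

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        first = next(iter(self.groups.values()))
        return first.amplitude / 4.0


@dataclass(frozen=True)
class SimulationSpec:
    """Design and ground truth for a synthetic cross-sectional cohort.

    ``n_per_cell`` is either a fixed subject count per group×timepoint
    cell, or an inclusive (lo, hi) range sampled uniformly per cell —
    the default (3, 6) mirrors typical per-cell sample sizes in circadian
    necropsy studies.
    """

    features: tuple[FeatureSpec, ...]
    period_h: float = DEFAULT_PERIOD_H
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_per_cell: int | tuple[int, int] = (3, 6)
    seed: int | None = None

    def validate(self) -> None:
        errors: list[str] = []
        if not self.features:
            errors.append("no features specified")
        if not (math.isfinite(self.period_h) and self.period_h > 0):
            errors.append(f"period_h must be positive, got {self.period_h}")
        else:
            folded = sorted(t % self.period_h for t in self.timepoints)
            if len(folded) < 2 or any(
                b - a < 1e-9 for a, b in zip(folded, folded[1:])
            ):
                errors.append("timepoints must be distinct modulo the period")
        for fs in self.features:
            sd = fs.resolved_noise_sd()
            if sd < 0:
                errors.append(f"{fs.name}: noise_sd must be >= 0, got {sd}")
            for g, truth in fs.groups.items():
                if truth.amplitude < 0:
                    errors.append(f"{fs.name}/{g}: amplitude must be >= 0")
                if not (0 <= truth.acrophase_h < self.period_h):
                    errors.append(
                        f"{fs.name}/{g}: acrophase_h must lie in [0, {self.period_h})"
                    )
        if isinstance(self.n_per_cell, tuple):
            lo, hi = self.n_per_cell
            if not (1 <= lo <= hi):
                errors.append(f"invalid n_per_cell range {self.n_per_cell}")
        elif self.n_per_cell < 1:
            errors.append(f"n_per_cell must be >= 1, got {self.n_per_cell}")
        if errors:
            raise InvalidArgumentError("invalid SimulationSpec: " + "; ".join(errors))


def _cell_sizes(spec: SimulationSpec, rng: np.random.Generator, n_cells: int) -> np.ndarray:
    if isinstance(spec.n_per_cell, tuple):
        lo, hi = spec.n_per_cell
        return rng.integers(lo, hi + 1, size=n_cells)
    return np.full(n_cells, spec.n_per_cell, dtype=int)


def cosine_value(truth: GroupTruth, time_h, period_h: float):
    """Noiseless model value M + A*cos(2*pi*(t - acrophase)/tau)."""
    omega = 2.0 * np.pi / period_h
    return truth.mesor + truth.amplitude * np.cos(
        omega * (np.asarray(time_h, dtype=float) - truth.acrophase_h)
    )


def simulate_cohort(spec: SimulationSpec, seed: int | None = None) -> CohortTable:
    """Draw a cross-sectional cohort from the spec's ground truth.

    For every feature, group, and timepoint, n subjects each contribute one
    value ``M + A*cos(2*pi*(t - acrophase)/tau) + Normal(0, noise_sd)``.
    Subject ids are unique within the cohort.  ``seed`` overrides
    ``spec.seed``; identical (spec, seed) give identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups_all = sorted({g for fs in spec.features for g in fs.groups})
    # one shared design (cell sizes) across features: same mice, many assays
    cells = [(g, t) for g in groups_all for t in spec.timepoints]
    sizes = _cell_sizes(spec, rng, len(cells))
    subject_ids = {}
    counter = 0
    for (g, t), n in zip(cells, sizes):
        ids = []
        for _ in range(int(n)):
            counter += 1
            ids.append(f"m{counter:04d}")
        subject_ids[(g, t)] = ids

    rows = []
    for fs in spec.features:
        sd = fs.resolved_noise_sd()
        for (g, t), ids in subject_ids.items():
            if g not in fs.groups:
                continue
            mean = cosine_value(fs.groups[g], t, spec.period_h)
            noise = rng.normal(0.0, sd, size=len(ids)) if sd > 0 else np.zeros(len(ids))
            for sid, eps in zip(ids, noise):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": g,
                        "time_h": float(t),
                        "feature": fs.name,
                        "value": float(mean + eps),
                    }
                )
    return CohortTable(data=pd.DataFrame(rows))


def simulate_null_cohort(spec: SimulationSpec, seed: int | None = None) -> CohortTable:
    """As :func:`simulate_cohort` with every amplitude forced to zero —
    the calibration null for the zero-amplitude test."""
    null_features = tuple(
        replace(
            fs,
            groups={
                g: GroupTruth(t.mesor, 0.0, 0.0) for g, t in fs.groups.items()
            },
            noise_sd=fs.resolved_noise_sd(),
        )
        for fs in spec.features
    )
    return simulate_cohort(replace(spec, features=null_features), seed=seed)


@dataclass(frozen=True)
class CommunitySpec:
    """Ground truth for a compositional, oscillating microbial community.

    ``baseline`` proportions lie on the simplex; taxon i's expected
    proportion at clock time t is ``baseline_i + amplitude_i *
    cos(2*pi*(t - acrophase_i)/tau)``, renormalized across taxa.  Group
    overrides replace (amplitude, acrophase) for named taxa in one group,
    letting two groups share a community but differ in specific
    oscillators.  Per sample, composition ~ Dirichlet(concentration ×
    expected) — ``concentration=inf`` means no overdispersion — and counts
    are multinomial at a lognormal library size (median
    ``library_median``, log-sd ``library_sigma``).
    """

    taxa: tuple[str, ...]
    baseline: tuple[float, ...]
    amplitude: tuple[float, ...]
    acrophase_h: tuple[float, ...]
    lineages: tuple[str, ...] | None = None
    concentration: float = 200.0
    library_median: float = 20000.0
    library_sigma: float = 0.25
    period_h: float = DEFAULT_PERIOD_H
    group_overrides: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    seed: int | None = None

    def validate(self) -> None:
        errors: list[str] = []
        k = len(self.taxa)
        if not (len(self.baseline) == len(self.amplitude) == len(self.acrophase_h) == k):
            errors.append("taxa/baseline/amplitude/acrophase lengths differ")
        else:
            if abs(sum(self.baseline) - 1.0) > 1e-9:
                errors.append("baseline proportions must sum to 1")
            for name, b, a in zip(self.taxa, self.baseline, self.amplitude):
                if b <= 0:
                    errors.append(f"{name}: baseline must be > 0")
                if a < 0:
                    errors.append(f"{name}: amplitude must be >= 0")
                if b - a <= 0:
                    errors.append(
                        f"{name}: amplitude {a} drives expected proportion <= 0 "
                        f"(baseline {b})"
                    )
        if self.lineages is not None and len(self.lineages) != k:
            errors.append("lineages length differs from taxa")
        if not (self.concentration > 0):
            errors.append("concentration must be > 0 (inf allowed)")
        if self.library_median <= 0 or self.library_sigma < 0:
            errors.append("invalid library-size parameters")
        for g, ov in self.group_overrides.items():
            for name, (a, acro) in ov.items():
                if name not in self.taxa:
                    errors.append(f"override for unknown taxon {name!r}")
                    continue
                b = self.baseline[self.taxa.index(name)]
                if a < 0 or b - a <= 0:
                    errors.append(f"{g}/{name}: override amplitude {a} invalid")
                if not (0 <= acro < self.period_h):
                    errors.append(f"{g}/{name}: override acrophase out of range")
        if errors:
            raise InvalidArgumentError("invalid CommunitySpec: " + "; ".join(errors))

    def params_for(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        amp = np.array(self.amplitude, dtype=float)
        acro = np.array(self.acrophase_h, dtype=float)
        for name, (a, ac) in self.group_overrides.get(group, {}).items():
            i = self.taxa.index(name)
            amp[i], acro[i] = a, ac
        return amp, acro


def _default_lineages(taxa: tuple[str, ...]) -> tuple[str, ...]:
    # synthetic flat taxonomy: every taxon its own genus under one phylum
    return tuple(
        f"Bacteria;SimPhylum;SimClass;SimOrder;SimFamily;{name}" for name in taxa
    )


def simulate_microbiome(
    spec: CommunitySpec,
    groups: tuple[str, ...] = ("wt", "ko"),
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    n_per_cell: int = 4,
    seed: int | None = None,
) -> TaxaTable:
    """Draw a sample×taxon count table from an oscillating community.

    Per sample at time t: expected proportions are the renormalized
    cosine-perturbed baseline; the realized composition is
    Dirichlet(concentration × expected) (or exactly the expected vector
    when concentration is inf); counts are multinomial at a library size
    drawn lognormally.  Counts sum exactly to the drawn library size.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    baseline = np.array(spec.baseline, dtype=float)
    omega = 2.0 * np.pi / spec.period_h
    lineages = spec.lineages or _default_lineages(spec.taxa)

    rows = {}
    meta_rows = []
    counter = 0
    for g in groups:
        amp, acro = spec.params_for(g)
        for t in timepoints:
            expected = baseline + amp * np.cos(omega * (t - acro))
            if np.any(expected <= 0):
                raise InvalidArgumentError(
                    f"expected proportions non-positive at t={t}, group={g}"
                )
            expected = expected / expected.sum()
            for _ in range(n_per_cell):
                counter += 1
                sid = f"s{counter:04d}"
                if np.isinf(spec.concentration):
                    comp = expected
                else:
                    comp = rng.dirichlet(spec.concentration * expected)
                lib = int(
                    round(
                        spec.library_median
                        * np.exp(rng.normal(0.0, spec.library_sigma))
                    )
                )
                lib = max(lib, 1)
                rows[sid] = rng.multinomial(lib, comp)
                meta_rows.append({"sample_id": sid, "group": g, "time_h": float(t)})

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(spec.taxa))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    taxonomy = dict(zip(spec.taxa, lineages))
    return TaxaTable(counts=counts, taxonomy=taxonomy, metadata=metadata, mode="counts")


def circular_mean_h(hours, period_h: float = DEFAULT_PERIOD_H) -> float:
    """Vector (resultant) mean of clock times on a circle of ``period_h``."""
    theta = 2.0 * np.pi * np.asarray(hours, dtype=float) / period_h
    mean_angle = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    h = float(np.mod(mean_angle * period_h / (2.0 * np.pi), period_h))
    return h if h < period_h else 0.0  # mod can round up to the period


def parameter_recovery(
    mesor: float,
    amplitude: float,
    acrophase_h: float,
    noise_sd: float | None = None,
    n_per_timepoint: int = 8,
    n_replicates: int = 500,
    period_h: float = DEFAULT_PERIOD_H,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
) -> dict[str, float]:
    """Simulate-and-refit recovery study for one ground-truth rhythm.

    Draws ``n_replicates`` independent cohorts (single group, fixed n per
    timepoint, Gaussian noise of sd ``noise_sd``, defaulting to
    amplitude/4), refits each with the single-cosinor estimator, and
    summarizes the sampling distribution of the estimates: mean MESOR,
    mean amplitude, and the circular mean of the fitted acrophases.
    """
    if noise_sd is None:
        noise_sd = amplitude / 4.0
    truth = GroupTruth(mesor, amplitude, acrophase_h)
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(timepoints, dtype=float), n_per_timepoint)
    mu = np.asarray(cosine_value(truth, t, period_h), dtype=float)

    mesors = np.empty(n_replicates)
    amps = np.empty(n_replicates)
    acros = np.empty(n_replicates)
    for i in range(n_replicates):
        y = mu + rng.normal(0.0, noise_sd, size=t.size)
        fit = fit_single_cosinor((t, y), period_h)
        mesors[i], amps[i], acros[i] = fit.mesor, fit.amplitude, fit.acrophase_h
    return {
        "mean_mesor": float(mesors.mean()),
        "mean_amplitude": float(amps.mean()),
        "circular_mean_acrophase_h": circular_mean_h(acros, period_h),
        "n_replicates": n_replicates,
        "n_per_cohort": int(t.size),
    }
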