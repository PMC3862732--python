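"""Synthetic paired-cohort generator.

Emulates the statistical structure of a paired bone-marrow / peripheral-blood
metabolomics study: 10 patients, BM and PB samples at days 0 and 29 of
induction therapy (PB additionally at day 8), log-normal metabolite
concentrations at physiological μM scales, configurable BM-minus-PB mean
shifts per day, block-correlated metabolite groups planted through a shared
latent Gaussian factor per block, and completely-at-random missingness.

Correlated blocks are built on the log scale: member ``m`` of a block with
target correlation ``r`` receives ``z = sqrt(r)·F + sqrt(1-r)·ε`` where ``F``
is the block's per-patient factor, so the log-scale pairwise correlation is
exactly ``r`` and the raw-scale correlation is the slightly attenuated
log-normal value (negligible at the default coefficient of variation 0.3).
Blocks can be active in BM values, PB values, or — the case the network
analysis interrogates — in the per-patient BM-minus-PB differences, where the
difference itself is generated as a positive log-normal excess added to the
lower compartment so every concentration stays strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ConcentrationTable
from .panels import PanelEntry, default_panel

SAMPLE_SCHEDULE = (("BM", 0), ("PB", 0), ("PB", 8), ("BM", 29), ("PB", 29))

SPACES = ("BM", "PB", "BM_minus_PB")


@dataclass(frozen=True)
class BlockSpec:
    """A planted correlated metabolite block.

    ``target_correlation`` is the intended pairwise correlation among the
    members, realized in ``active_space`` (BM values, PB values, or BM-PB
    per-patient differences) at ``active_day``.
    """

    members: tuple
    target_correlation: float
    active_day: int
    active_space: str = "BM_minus_PB"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("block needs at least 2 members")
        if not -1.0 < self.target_correlation < 1.0:
            raise ValueError("target correlation must be in (-1, 1)")
        if self.active_space not in SPACES:
            raise ValueError(f"active_space must be one of {SPACES}")


@dataclass
class CohortConfig:
    n_patients: int = 10
    panel: list = field(default_factory=default_panel)
    blocks: list = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = set()
        for entry in self.panel:
            if entry.mean <= 0:
                raise ValueError(f"non-positive mean for {entry.name!r}")
            names.add(entry.name)
        for block in self.blocks:
            stray = set(block.members) - names
            if stray:
                raise ValueError(f"block members not in panel: {sorted(stray)}")


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognormal(mean: float, sigma: float, z: np.ndarray) -> np.ndarray:
    # E[mean * exp(sigma z - sigma^2/2)] = mean for standard normal z
    return mean * np.exp(sigma * z - 0.5 * sigma * sigma)


def generate_cohort(config: CohortConfig) -> ConcentrationTable:
    """Generate a paired cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"patient_{i + 1:02d}" for i in range(n)]
    entries = {e.name: e for e in config.panel}

    # block membership lookup: (name, space, day) -> (block index, loading)
    member_of: dict = {}
    for b_idx, block in enumerate(config.blocks):
        for pos, m in enumerate(block.members):
            key = (m, block.active_space, block.active_day)
            if key in member_of:
                raise ValueError(f"{m!r} is in two blocks active in the same space/day")
            member_of[key] = (b_idx, block.target_correlation, pos)
    factors = rng.standard_normal((len(config.blocks), n))

    def draw_z(name: str, space: str, day: int) -> np.ndarray:
        eps = rng.standard_normal(n)
        hit = member_of.get((name, space, day))
        if hit is None:
            return eps
        b_idx, rho, pos = hit
        # negative targets alternate loading signs (exactly -|rho| for pairs
        # of opposite sign; only meaningful for 2-member blocks)
        sign = 1.0 if rho >= 0 else (-1.0) ** pos
        a = sign * math.sqrt(abs(rho))
        return a * factors[b_idx] + math.sqrt(1.0 - abs(rho)) * eps

    columns: dict = {}
    index = pd.MultiIndex.from_tuples(
        [(p, c, d) for p in patients for c, d in SAMPLE_SCHEDULE],
        names=["patient_id", "compartment", "day"],
    )
    for name, entry in entries.items():
        sigma = _sigma(entry.cv)
        values = {}
        for comp, day in SAMPLE_SCHEDULE:
            shift = entry.shift(day) if comp == "BM" else 0.0
            mean = entry.mean + shift
            mean = max(mean, 0.05 * entry.mean)  # keep strictly positive scale
            values[(comp, day)] = _lognormal(mean, sigma, draw_z(name, comp, day))
        # difference-space blocks: regenerate the pair so the per-patient
        # BM-PB difference is a correlated positive log-normal excess
        for comp_day in (0, 29):
            hit = member_of.get((name, "BM_minus_PB", comp_day))
            if hit is None:
                continue
            shift = entry.shift(comp_day)
            scale = abs(shift) if shift != 0.0 else 0.25 * entry.mean
            excess = _lognormal(scale, sigma, draw_z(name, "BM_minus_PB", comp_day))
            base = _lognormal(entry.mean, sigma, rng.standard_normal(n))
            if shift >= 0:
                values[("PB", comp_day)] = base
                values[("BM", comp_day)] = base + excess
            else:
                values[("BM", comp_day)] = base
                values[("PB", comp_day)] = base + excess
        col = np.empty(len(index))
        for i, p in enumerate(patients):
            for j, (c, d) in enumerate(SAMPLE_SCHEDULE):
                col[i * len(SAMPLE_SCHEDULE) + j] = values[(c, d)][i]
        columns[name] = col

    table = ConcentrationTable(pd.DataFrame(columns, index=index))
    if config.missing_rate > 0:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missing(table, config.missing_rate, sub_seed)
    return table


def inject_missing(table: ConcentrationTable, rate: float, seed: int) -> ConcentrationTable:
    """Set each cell missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return ConcentrationTable(table.data.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(table.data.shape) < rate
    data = table.data.where(~mask)
    return ConcentrationTable(data)


def generate_feature_matrix(
    n_subjects: int,
    n_features: int,
    class_effect: float,
    seed: int,
    noise_sd: float = 1.0,
):
    """Paired two-class feature matrix (a proxy for binned spectra).

    Each subject contributes two rows, one per class; ``class_effect``
    controls the within-subject separation along a fixed pattern over the
    first half of the features. ``class_effect = 0`` gives exchangeable
    pairs, the null configuration for permutation calibration.

    Returns ``(X, subjects, labels)`` with ``X`` of shape
    ``(2·n_subjects, n_features)``, subject ids, and labels ``-1 / +1``.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    pattern = np.zeros(n_features)
    half = max(1, n_features // 2)
    pattern[:half] = 1.0 / math.sqrt(half)
    between = rng.standard_normal((n_subjects, n_features)) * 2.0
    X = np.empty((2 * n_subjects, n_features))
    subjects = np.empty(2 * n_subjects, dtype=object)
    labels = np.empty(2 * n_subjects, dtype=int)
    for s in range(n_subjects):
        for k, cls in enumerate((-1, +1)):
            row = (
                between[s]
                + 0.5 * cls * class_effect * pattern
                + noise_sd * rng.standard_normal(n_features)
            )
            X[2 * s + k] = row
            subjects[2 * s + k] = f"subject_{s + 1:02d}"
            labels[2 * s + k] = cls
    return X, subjects, labels
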