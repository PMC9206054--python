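"""Generative simulator for lineup trials and simulation-based power analysis.

The simulator makes the analysis' statistical assumptions executable: each
lineup member contributes an independent memory-strength draw (fillers
standard normal, the target N(mu_t, sigma_t)), the strongest member is
identified iff it exceeds the lowest confidence criterion, and the
confidence band is the highest criterion exceeded.  Response times follow
a lognormal whose location decreases with the decision margin (the
strength of the winning face above the identification criterion), so
stronger evidence produces faster responses — the structure the RAC
analysis assumes.  Rejection confidence comes from thresholds below c_1:
the further the strongest face falls below the identification criterion,
the more certain the "not present" response.

The power analysis simulates two conditions from fitted model parameters
at a grid of sample sizes and runs the full ROC/pAUC bootstrap Z-test per
replicate, reporting the rejection rate at each n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    BinningScheme,
    Condition,
    Group,
    LineupOutcomeTable,
    LineupType,
    Response,
    TrialRecord,
    tabulate,
)
from .roc import pauc_z_test
from .sdt import SDTParams

__all__ = [
    "RTModel",
    "SimulationConfig",
    "PowerResult",
    "simulate_trials",
    "expand",
    "power_analysis",
]


@dataclass(frozen=True)
class RTModel:
    """Lognormal response-time model: ``rt = exp(log(base) - slope * margin
    + noise)`` with ``noise ~ N(0, noise_sd)`` on the log scale and
    ``margin`` the strength of the strongest face relative to the
    identification criterion.  ``base`` (seconds) is the typical RT of a
    decision made exactly at criterion; positive ``slope`` makes
    high-margin (strong-evidence) decisions faster."""

    base: float = 10.0
    slope: float = 0.35
    noise_sd: float = 0.45

    def __post_init__(self) -> None:
        if self.base <= 0 or self.noise_sd < 0:
            raise ValueError("base must be positive and noise_sd nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-cell simulation settings.

    ``params.criteria`` may hold one criterion per raw confidence level
    (7) or one per bin of ``scheme``; confidence ratings are emitted as
    the lowest raw level of the band's bin so that re-binning with the
    same scheme recovers the bands exactly.  ``rejection_criteria``
    (ascending, all below c_1) grade no-ID confidence; if None they are
    evenly spaced 0.4 apart below c_1.
    """

    params: SDTParams
    n_tp: int
    n_ta: int
    seed: int
    rt_model: RTModel = field(default_factory=RTModel)
    rejection_criteria: tuple[float, ...] | None = None
    scheme: BinningScheme = field(default_factory=BinningScheme)
    group: Group = Group.YOUNG
    condition: Condition = Condition.CONTROL

    def __post_init__(self) -> None:
        if self.n_tp < 0 or self.n_ta < 0:
            raise ValueError("n_tp and n_ta must be nonnegative")
        m = self.params.n_bands
        if m not in (7, self.scheme.n_confidence_bins):
            raise ValueError(
                f"{m} criteria match neither the 7-point scale nor the "
                f"{self.scheme.n_confidence_bins} bins of the scheme"
            )
        if self.rejection_criteria is not None:
            rc = tuple(float(b) for b in self.rejection_criteria)
            if any(b2 <= b1 for b1, b2 in zip(rc, rc[1:])):
                raise ValueError("rejection criteria must be strictly increasing")
            if rc and rc[-1] >= self.params.criteria[0]:
                raise ValueError("rejection criteria must lie below c_1")
            object.__setattr__(self, "rejection_criteria", rc)

    def id_confidence_levels(self) -> np.ndarray:
        """Raw confidence rating emitted for each ID band."""
        m = self.params.n_bands
        if m == 7:
            return np.arange(1, 8)
        return np.array([b[0] for b in self.scheme.confidence_bins])

    def effective_rejection_criteria(self) -> np.ndarray:
        if self.rejection_criteria is not None:
            return np.asarray(self.rejection_criteria)
        c1 = self.params.criteria[0]
        n_bands = len(self.id_confidence_levels())
        return c1 - 0.4 * np.arange(n_bands - 1, 0, -1)


def _no_id_confidence_levels(config: SimulationConfig) -> np.ndarray:
    """Raw rating per rejection band, *most* certain first matched to the
    highest rating: a strongest face far below c_1 supports a confident
    "not present"."""
    return config.id_confidence_levels()


def simulate_trials(config: SimulationConfig) -> list[TrialRecord]:
    """Simulate one study cell of target-present and target-absent lineups.

    Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    crit = np.asarray(p.criteria)
    rej = config.effective_rejection_criteria()
    id_levels = config.id_confidence_levels()
    no_id_levels = _no_id_confidence_levels(config)
    records: list[TrialRecord] = []

    def emit(
        lineup_type: LineupType,
        strengths: np.ndarray,
        target_col: int | None,
        offset: int,
    ) -> None:
        n = strengths.shape[0]
        if n == 0:
            return
        s_max = strengths.max(axis=1)
        winner = strengths.argmax(axis=1)
        identified = s_max >= crit[0]
        band = np.searchsorted(crit, s_max, side="right") - 1  # valid where identified
        rej_band = np.searchsorted(rej, s_max, side="right")  # 0 = far below c_1
        margin = s_max - crit[0]
        log_rt = (
            np.log(config.rt_model.base)
            - config.rt_model.slope * margin
            + rng.normal(0.0, config.rt_model.noise_sd, size=n)
        )
        rt = np.exp(log_rt)
        for i in range(n):
            if identified[i]:
                resp = (
                    Response.SUSPECT_ID
                    if target_col is not None and winner[i] == target_col
                    else Response.FILLER_ID
                )
                conf = int(id_levels[band[i]])
            else:
                resp = Response.NO_ID
                # deeper below c_1 (smaller rej_band) -> higher confidence
                idx = len(rej) - rej_band[i]
                conf = int(no_id_levels[min(idx, len(no_id_levels) - 1)])
            records.append(
                TrialRecord(
                    participant_id=f"sim{offset + i:06d}",
                    group=config.group,
                    condition=config.condition,
                    lineup_type=lineup_type,
                    response=resp,
                    confidence=conf,
                    rt=float(rt[i]),
                )
            )

    tp = np.empty((config.n_tp, p.k))
    tp[:, 0] = rng.normal(p.mu_t, p.sigma_t, size=config.n_tp)
    tp[:, 1:] = rng.normal(p.mu_l, p.sigma_l, size=(config.n_tp, p.k - 1))
    emit(LineupType.TARGET_PRESENT, tp, target_col=0, offset=0)
    ta = rng.normal(p.mu_l, p.sigma_l, size=(config.n_ta, p.k))
    emit(LineupType.TARGET_ABSENT, ta, target_col=None, offset=config.n_tp)
    return records


def expand(
    table: LineupOutcomeTable, seed: int | None = None
) -> list[TrialRecord]:
    """One trial record per table count (response times absent).

    Inverse of :func:`lineup_sdt.data.tabulate` up to record order; pass
    ``seed`` to shuffle the emitted records reproducibly.
    """
    group = Group(table.meta.get("group", "young"))
    condition = Condition(table.meta.get("condition", "control"))
    records: list[TrialRecord] = []
    idx = 0
    for lt, resp, vec in (
        (LineupType.TARGET_PRESENT, Response.SUSPECT_ID, table.tp_suspect),
        (LineupType.TARGET_PRESENT, Response.FILLER_ID, table.tp_filler),
        (LineupType.TARGET_PRESENT, Response.NO_ID, table.tp_no_id),
        (LineupType.TARGET_ABSENT, Response.FILLER_ID, table.ta_filler),
        (LineupType.TARGET_ABSENT, Response.NO_ID, table.ta_no_id),
    ):
        for level, count in zip(table.levels, vec):
            for _ in range(count):
                records.append(
                    TrialRecord(
                        participant_id=f"exp{idx:06d}",
                        group=group,
                        condition=condition,
                        lineup_type=lt,
                        response=resp,
                        confidence=level[0],
                    )
                )
                idx += 1
    if seed is not None:
        np.random.default_rng(seed).shuffle(records)
    return records


@dataclass(frozen=True)
class PowerResult:
    """Rejection rates of the pAUC Z-test per simulated sample size."""

    n_grid: tuple[int, ...]
    rejection_rate: tuple[float, ...]
    mean_abs_z: tuple[float, ...]
    n_skipped: tuple[int, ...]
    n_sim: int
    n_boot: int
    alpha: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_sim": self.n_sim,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "per_n": [
                {
                    "n": n,
                    "rejection_rate": r,
                    "mean_abs_z": z,
                    "n_skipped": s,
                }
                for n, r, z, s in zip(
                    self.n_grid, self.rejection_rate, self.mean_abs_z, self.n_skipped
                )
            ],
        }


def power_analysis(
    params_a: SDTParams,
    params_b: SDTParams,
    n_grid: list[int],
    n_boot: int = 2000,
    n_sim: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: BinningScheme | None = None,
    rt_model: RTModel | None = None,
) -> PowerResult:
    """Simulation-based power of the pAUC Z-test.

    For each per-cell lineup count ``n`` and each of ``n_sim`` replicates,
    both conditions are simulated from their generating parameters, the
    trials tabulated and binned, and the full ROC/pAUC bootstrap Z-test
    run with ``n_boot`` replicates; power is the fraction of replicates
    with two-sided p < ``alpha``.  Replicates where a condition produced
    no identifications at all are skipped and counted.
    """
    if not n_grid:
        raise ValueError("n_grid must be nonempty")
    scheme = scheme or BinningScheme()
    rt_model = rt_model or RTModel()
    root = np.random.SeedSequence(seed)
    rates, mean_zs, skips = [], [], []
    for n in n_grid:
        n_reject = 0
        n_done = 0
        n_skip = 0
        zs = []
        for ss in root.spawn(n_sim):
            s_a, s_b, s_boot = ss.spawn(3)
            tables = []
            for params, s in ((params_a, s_a), (params_b, s_b)):
                cfg = SimulationConfig(
                    params=params,
                    n_tp=n,
                    n_ta=n,
                    seed=int(s.generate_state(1)[0] % 2**31),
                    rt_model=rt_model,
                    scheme=scheme,
                )
                tables.append(tabulate(simulate_trials(cfg), k=params.k))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cmp = pauc_z_test(
                        tables[0],
                        tables[1],
                        scheme,
                        n_boot=n_boot,
                        seed=int(s_boot.generate_state(1)[0] % 2**31),
                    )
                except ValueError:
                    n_skip += 1
                    continue
            if not np.isfinite(cmp.z):
                n_skip += 1
                continue
            n_done += 1
            zs.append(abs(cmp.z))
            if cmp.p < alpha:
                n_reject += 1
        rates.append(n_reject / n_done if n_done else float("nan"))
        mean_zs.append(float(np.mean(zs)) if zs else float("nan"))
        skips.append(n_skip)
    return PowerResult(
        n_grid=tuple(int(n) for n in n_grid),
        rejection_rate=tuple(rates),
        mean_abs_z=tuple(mean_zs),
        n_skipped=tuple(skips),
        n_sim=n_sim,
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
    )
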