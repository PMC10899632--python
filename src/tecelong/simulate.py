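"""Continuous-time Markov simulation of single TECs elongating through
chromatin, plus the exact transient-distribution oracle.

The model is a pure birth chain over transcript lengths ``stall..full``:

* the stalled state empties at rate ``k_release`` (escape from +58);
* every other single-nucleotide addition occurs at rate ``k_step``, divided
  by the barrier factor beta of the position being stepped *into* when that
  position is a barrier-encounter site;
* the full-length state is absorbing.

TFS (the cleavage-stimulatory factor) is modeled as two multipliers: it
scales ``k_release`` up by ``tfs_release_mult`` and divides barrier factors
by ``tfs_barrier_mult`` (never below 1 — TFS cannot outrun the barrier-free
stepping rate).  Backtracked states are not modeled explicitly; pausing here
is not backtracking but waiting for an effective barrier-escape event, and
histone dissociation/exchange is subsumed into that escape rate.

Dwell times are exponential, so ensembles can be sampled exactly (no time
discretization): per-molecule arrival times at each length are cumulative
sums of independent exponentials, and the length at an observation time is
read off by binary search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .binning import BinScheme, default_bin_scheme
from .template import (
    ChromatinLandscape,
    TemplateDesign,
    default_template,
    make_landscape,
)

__all__ = [
    "SimulationParams",
    "LengthDistribution",
    "StudyCondition",
    "CONDITION_KINETICS",
    "position_rate",
    "rate_vector",
    "simulate_ensemble",
    "transient_distribution",
    "default_study_conditions",
    "generate_study",
    "DEFAULT_OBS_TIMES",
    "EXTENDED_OBS_TIMES",
]

DEFAULT_OBS_TIMES: tuple[float, ...] = (15.0, 30.0, 60.0, 120.0, 240.0)
EXTENDED_OBS_TIMES: tuple[float, ...] = (15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0)

# Molecules sampled per fixed-size block, each block on its own child RNG
# stream, so results for a given (seed, n_molecules) do not depend on how
# the blocks are executed.
_CHUNK = 10_000


@dataclass(frozen=True)
class SimulationParams:
    """Rate constants and observation design for one ensemble.

    k_step : barrier-free single-nucleotide addition rate (nt/s).
    k_release : escape rate from the stalled state (1/s).
    tfs_release_mult : factor (>= 0) on k_release when TFS is present.
    tfs_barrier_mult : divisor (>= 1) on barrier factors when TFS is present.
    tfs : whether TFS is present in this reaction.
    """

    k_step: float = 12.0
    k_release: float = 0.005
    tfs_release_mult: float = 1.0
    tfs_barrier_mult: float = 1.0
    tfs: bool = False
    n_molecules: int = 1000
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_step <= 0 or self.k_release <= 0:
            raise ValueError("k_step and k_release must be positive")
        if self.tfs_release_mult < 0:
            raise ValueError("tfs_release_mult must be non-negative")
        if self.tfs_barrier_mult < 1:
            raise ValueError("tfs_barrier_mult must be >= 1")
        t = self.obs_times
        if len(t) == 0 or any(x <= 0 for x in t) or any(
            a >= b for a, b in zip(t, t[1:])
        ):
            raise ValueError("obs_times must be positive and strictly increasing")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class LengthDistribution:
    """Transcript-length distribution of an ensemble at one timepoint."""

    time_s: float
    lengths: np.ndarray  # nt, ascending
    counts: np.ndarray  # counts or probability mass per length
    n_total: float

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.counts):
            raise ValueError("lengths and counts must align")

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_total

    @property
    def mean_length(self) -> float:
        return float(np.dot(self.lengths, self.fractions))

    def bin_fractions(self, scheme: BinScheme | None = None) -> np.ndarray:
        scheme = scheme or default_bin_scheme()
        return scheme.fractions(self.lengths, self.counts)


def _effective_beta(beta: float, params: SimulationParams) -> float:
    if params.tfs and beta > 1.0:
        return max(beta / params.tfs_barrier_mult, 1.0)
    return beta


def position_rate(
    L: int,
    params: SimulationParams,
    landscape: ChromatinLandscape,
    template: TemplateDesign | None = None,
) -> float:
    """Rate (1/s) of leaving transcript length ``L`` toward ``L+1``.

    At the stall this is the release rate; elsewhere the stepping rate
    divided by the barrier factor of the position being entered.
    """
    template = template or default_template()
    if L < template.stall_pos or L >= template.full_length:
        raise ValueError(
            f"L={L} outside elongating range "
            f"[{template.stall_pos}, {template.full_length})"
        )
    if L == template.stall_pos:
        rate = params.k_release
        if params.tfs:
            rate *= params.tfs_release_mult
        return rate
    beta = _effective_beta(landscape.factor_at(L + 1), params)
    return params.k_step / beta


def rate_vector(
    params: SimulationParams,
    landscape: ChromatinLandscape,
    template: TemplateDesign | None = None,
) -> np.ndarray:
    """Per-state exit rates for lengths ``stall .. full-1`` (vectorized)."""
    template = template or default_template()
    rates = np.full(template.n_states - 1, params.k_step)
    rates[0] = params.k_release * (params.tfs_release_mult if params.tfs else 1.0)
    for pos, beta in zip(landscape.barrier_positions, landscape.barrier_factors):
        idx = pos - template.stall_pos - 1  # step index entering `pos`
        if 0 <= idx < len(rates) and idx != 0:
            rates[idx] = params.k_step / _effective_beta(beta, params)
    return rates


def simulate_ensemble(
    params: SimulationParams,
    landscape: ChromatinLandscape,
    template: TemplateDesign | None = None,
) -> list[LengthDistribution]:
    """Sample ``n_molecules`` independent trajectories; return the length
    distribution at each observation time.

    Reproducible bit-exactly for a given seed.  Memory stays bounded by
    sampling molecules in fixed-size blocks, each on its own child stream of
    the master seed.
    """
    template = template or default_template()
    rates = rate_vector(params, landscape, template)
    n_states = template.n_states
    obs = np.asarray(params.obs_times, dtype=float)
    counts = np.zeros((len(obs), n_states), dtype=np.int64)

    n = params.n_molecules
    n_chunks = (n + _CHUNK - 1) // _CHUNK
    children = np.random.SeedSequence(params.seed).spawn(n_chunks)
    for c in range(n_chunks):
        m = min(_CHUNK, n - c * _CHUNK)
        rng = np.random.default_rng(children[c])
        dwells = rng.exponential(1.0 / rates, size=(m, len(rates)))
        arrivals = np.cumsum(dwells, axis=1)
        for j, t in enumerate(obs):
            # number of completed steps by time t = state index
            state = (arrivals <= t).sum(axis=1)
            counts[j] += np.bincount(state, minlength=n_states)

    lengths = np.arange(template.stall_pos, template.full_length + 1)
    return [
        LengthDistribution(time_s=float(t), lengths=lengths, counts=counts[j],
                           n_total=float(n))
        for j, t in enumerate(obs)
    ]


def transient_distribution(
    params: SimulationParams,
    landscape: ChromatinLandscape,
    template: TemplateDesign | None = None,
    t: float = 0.0,
) -> LengthDistribution:
    """Exact state probabilities of the birth chain at time ``t``.

    Solves p(t) = p(0) e^{Qt} with the dense matrix exponential of the
    bidiagonal generator; deterministic, no sampling error.  Serves as the
    oracle against which the sampler is validated.
    """
    template = template or default_template()
    if t < 0:
        raise ValueError("t must be non-negative")
    rates = rate_vector(params, landscape, template)
    if not np.all(np.isfinite(rates)):
        raise ValueError("non-finite rates")
    n = template.n_states
    Q = np.zeros((n, n))
    idx = np.arange(n - 1)
    Q[idx, idx] = -rates
    Q[idx, idx + 1] = rates
    p0 = np.zeros(n)
    p0[0] = 1.0
    p = p0 @ expm(Q * t)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    lengths = np.arange(template.stall_pos, template.full_length + 1)
    return LengthDistribution(time_s=float(t), lengths=lengths, counts=p, n_total=1.0)


# ---------------------------------------------------------------------------
# Study generation: the full multi-condition, multi-replicate design.

# Per-variant release kinetics of the stalled complex.  Values are the
# generator's emulation of the measured condition structure: release rates
# are anchored at WT = 0.005/s and scaled by each variant's relative
# half-life at +58; the TFS release multiplier is the ratio of -TFS to +TFS
# relative half-lives.  The TFS barrier divisor is >1 only for the variants
# whose prominent +70 pause is reduced by TFS (E19K, G17D); the double
# mutant's pause is TFS-resistant.
_WT_K_RELEASE = 0.005
_REL_HALF_LIFE = {
    # variant: (relative t1/2 -TFS, relative t1/2 +TFS)
    "HTkA-free": (0.28, 0.19),
    "WT": (1.00, 0.54),
    "G17D": (0.65, 0.40),
    "E19K": (0.84, 0.59),
    "G52K": (0.77, 0.38),
    "E19K/G52K": (0.44, 0.41),
    "R20S": (0.30, 0.18),
    "T55L": (0.28, 0.17),
    "E3A": (0.27, 0.19),
    "E34A": (0.56, 0.29),
}
CONDITION_KINETICS: dict[str, dict[str, float]] = {
    name: {
        "k_release": _WT_K_RELEASE / rel_minus,
        "tfs_release_mult": rel_minus / rel_plus,
        "tfs_barrier_mult": 2.0 if name in ("E19K", "G17D") else 1.0,
    }
    for name, (rel_minus, rel_plus) in _REL_HALF_LIFE.items()
}


@dataclass(frozen=True)
class StudyCondition:
    variant: str
    tfs: bool
    n_replicates: int


def default_study_conditions() -> list[StudyCondition]:
    """Ten chromatin landscapes, each with 4 replicates without TFS and 3
    with TFS (the study's replicate structure)."""
    order = [
        "HTkA-free", "T55L", "R20S", "E3A", "WT",
        "G52K", "E34A", "G17D", "E19K", "E19K/G52K",
    ]
    out = []
    for v in order:
        out.append(StudyCondition(v, tfs=False, n_replicates=4))
        out.append(StudyCondition(v, tfs=True, n_replicates=3))
    return out


def params_for_condition(
    variant: str,
    tfs: bool,
    n_molecules: int = 1000,
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES,
    seed: int = 0,
    k_step: float = 12.0,
) -> SimulationParams:
    """Default rate constants for a named variant condition."""
    kin = CONDITION_KINETICS.get(variant)
    if kin is None:
        raise KeyError(f"no default kinetics for variant {variant!r}")
    return SimulationParams(
        k_step=k_step,
        k_release=kin["k_release"],
        tfs_release_mult=kin["tfs_release_mult"],
        tfs_barrier_mult=kin["tfs_barrier_mult"],
        tfs=tfs,
        n_molecules=n_molecules,
        obs_times=obs_times,
        seed=seed,
    )


def generate_study(
    master_seed: int,
    conditions: list[StudyCondition] | None = None,
    template: TemplateDesign | None = None,
    scheme: BinScheme | None = None,
    n_molecules: int = 1000,
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES,
    extended: bool = False,
) -> pd.DataFrame:
    """Simulate the full study design and return the binned fraction table.

    One row per (condition, tfs, replicate, timepoint) with columns
    ``bin1..bin7``; replicate seeds are derived independently from the
    master seed so the table is byte-identical on rerun.
    """
    template = template or default_template()
    scheme = scheme or default_bin_scheme()
    conditions = conditions if conditions is not None else default_study_conditions()
    if extended:
        obs_times = EXTENDED_OBS_TIMES
    labels = [(c.variant, c.tfs) for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")

    ss = np.random.SeedSequence(master_seed)
    rep_seeds = ss.generate_state(sum(c.n_replicates for c in conditions) * 2)
    rows = []
    k = 0
    for cond in conditions:
        landscape = make_landscape(template, cond.variant)
        for rep in range(1, cond.n_replicates + 1):
            seed = int(rep_seeds[k] % (2**31 - 1))
            k += 1
            params = params_for_condition(
                cond.variant, cond.tfs, n_molecules=n_molecules,
                obs_times=obs_times, seed=seed,
            )
            for dist in simulate_ensemble(params, landscape, template):
                f = dist.bin_fractions(scheme)
                rows.append(
                    {
                        "condition": cond.variant,
                        "tfs": int(cond.tfs),
                        "replicate": rep,
                        "time_s": dist.time_s,
                        **{f"bin{b+1}": f[b] for b in range(7)},
                    }
                )
    return pd.DataFrame(rows)
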