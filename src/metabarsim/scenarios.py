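"""Factorial simulation design: richness x concentration x efficiency variation.

A scenario grid crosses community richness, a shared template concentration
``lambda`` (copies/uL), and an efficiency-concentration parameter ``gamma``.
Species efficiencies are drawn ``a ~ Beta(0.7*gamma, 0.3*gamma)`` so the mean
efficiency is 0.7 at every gamma while the spread shrinks as gamma grows
(gamma = 5 is strong among-species variation, gamma = 1e6 effectively none).
Each realization simulates one technical replicate of a fresh community and
emits one record per species, retaining W (templates in the tube) and Y
(observed reads) so the non-detection decomposition

    p(Y=0) = p(W=0) + p(Y=0 | W>0) * (1 - p(W=0))

can be tabulated from the same counts; p(Y=0 | W=0) = 1 holds structurally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CommunityProfile,
    ProtocolParams,
    draw_template_counts,
    amplify_first_pcr,
    subsample_cleanup,
    amplify_index_pcr,
    compute_read_proportions,
    draw_reads,
)
from .errors import DegenerateReplicateError, EmptyInputError, InvalidParameterError

__all__ = [
    "DEFAULT_LAMBDA_LEVELS",
    "DEFAULT_GAMMA_LEVELS",
    "DEFAULT_RICHNESS_LEVELS",
    "ScenarioGrid",
    "ScenarioSpec",
    "draw_efficiencies",
    "default_lambda_levels",
    "build_scenario_grid",
    "build_community",
    "run_scenario",
    "run_grid",
    "summarize_nondetection",
    "summarize_reads",
]

#: Mean amplification efficiency of the Beta sampler, fixed across gamma.
MEAN_EFFICIENCY = 0.7

DEFAULT_RICHNESS_LEVELS = (4, 10, 30, 50)
DEFAULT_GAMMA_LEVELS = (5.0, 10.0, 20.0, 100.0, 1_000.0, 1_000_000.0)

#: Scenario-record column order used by run_scenario / run_grid.
RECORD_COLUMNS = [
    "richness", "lambda_level", "gamma", "profile",
    "realization", "species", "efficiency", "lam",
    "W", "Y", "n_reads", "degenerate",
]


def default_lambda_levels(n_levels: int = 18,
                          low: float = 0.5,
                          high: float = 10_000.0) -> np.ndarray:
    """Logarithmically spaced template-concentration levels (copies/uL)."""
    return np.geomspace(low, high, n_levels)


DEFAULT_LAMBDA_LEVELS = default_lambda_levels()


def draw_efficiencies(
    gamma: float,
    n_species: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw species efficiencies a_i ~ Beta(0.7*gamma, 0.3*gamma), i.i.d.

    The Beta mean is 0.7 for every gamma; the variance 0.21/(gamma + 1)
    controls among-species amplification bias.
    """
    if gamma <= 0:
        raise InvalidParameterError("gamma must be > 0")
    if n_species < 1:
        raise InvalidParameterError("need at least one species")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return rng.beta(MEAN_EFFICIENCY * gamma, (1 - MEAN_EFFICIENCY) * gamma, n_species)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design with its reproducible substream seed."""

    index: int
    richness: int
    lambda_level: float
    gamma: float
    profile: str
    weights: tuple[float, ...] | None
    seed_seq: np.random.SeedSequence


@dataclass
class ScenarioGrid:
    """Cartesian product of richness x lambda x gamma levels.

    Each scenario receives a deterministic child of the master seed, so the
    full grid is reproducible and scenarios can run in any order.
    """

    richness_levels: list[int]
    lambda_levels: list[float]
    gamma_levels: list[float]
    n_realizations: int = 2_000
    master_seed: int = 0
    abundance_profile: dict[str, list[float]] | None = None

    def __post_init__(self) -> None:
        if not (self.richness_levels and list(self.lambda_levels) and self.gamma_levels):
            raise InvalidParameterError("level lists must be non-empty")
        if any(r < 1 for r in self.richness_levels):
            raise InvalidParameterError("richness levels must be >= 1")
        if any(l <= 0 for l in self.lambda_levels):
            raise InvalidParameterError("lambda levels must be > 0")
        if any(g <= 0 for g in self.gamma_levels):
            raise InvalidParameterError("gamma levels must be > 0")
        if self.n_realizations < 1:
            raise InvalidParameterError("n_realizations must be >= 1")

    @property
    def n_scenarios(self) -> int:
        return (len(self.richness_levels) * len(list(self.lambda_levels))
                * len(self.gamma_levels))

    def entries(self) -> list[ScenarioSpec]:
        """Enumerate scenarios in deterministic (richness, lambda, gamma) order."""
        children = np.random.SeedSequence(self.master_seed).spawn(self.n_scenarios)
        profile = self.abundance_profile
        entries = []
        combos = itertools.product(
            self.richness_levels, list(self.lambda_levels), self.gamma_levels
        )
        for idx, (richness, lam, gamma) in enumerate(combos):
            label, weights = "even", None
            if profile is not None:
                # one named profile applies to matching-richness scenarios
                for name, w in profile.items():
                    if len(w) == richness:
                        label, weights = name, tuple(float(x) for x in w)
                        break
            entries.append(ScenarioSpec(idx, int(richness), float(lam), float(gamma),
                                        label, weights, children[idx]))
        return entries


def build_scenario_grid(
    richness_levels=DEFAULT_RICHNESS_LEVELS,
    lambda_levels=None,
    gamma_levels=DEFAULT_GAMMA_LEVELS,
    n_realizations: int = 2_000,
    master_seed: int = 0,
    abundance_profile=None,
) -> ScenarioGrid:
    """Build the factorial design; defaults give the 4 x 18 x 6 = 432-cell grid."""
    if lambda_levels is None:
        lambda_levels = DEFAULT_LAMBDA_LEVELS
    return ScenarioGrid(
        richness_levels=list(richness_levels),
        lambda_levels=list(np.asarray(lambda_levels, dtype=float)),
        gamma_levels=list(gamma_levels),
        n_realizations=n_realizations,
        master_seed=master_seed,
        abundance_profile=abundance_profile,
    )


def build_community(
    richness: int,
    lambda_level: float,
    efficiencies: np.ndarray,
    abundance_profile=None,
) -> CommunityProfile:
    """Assemble a community at a shared concentration level.

    Even communities give every species ``lambda_level`` copies/uL.  An
    uneven profile supplies raw weights; concentrations are scaled so their
    mean stays at ``lambda_level`` (lambda_i = level * w_i / mean(w)).
    """
    efficiencies = np.asarray(efficiencies, dtype=float)
    if efficiencies.shape != (richness,):
        raise InvalidParameterError("efficiency vector length must equal richness")
    if abundance_profile is None:
        lam = np.full(richness, float(lambda_level))
    else:
        w = np.asarray(abundance_profile, dtype=float)
        if w.shape != (richness,):
            raise InvalidParameterError("abundance profile length must equal richness")
        if np.any(w <= 0):
            raise InvalidParameterError("abundance weights must be > 0")
        lam = lambda_level * w / w.mean()
    ids = [f"sp{i + 1:03d}" for i in range(richness)]
    return CommunityProfile(ids, lam, efficiencies)


def run_scenario(
    entry: ScenarioSpec,
    protocol: ProtocolParams,
    n_realizations: int,
    rng: np.random.Generator | None = None,
    redraw_efficiencies: bool = True,
) -> pd.DataFrame:
    """Simulate one scenario and return a tidy per-(realization, species) table.

    By default a fresh efficiency vector is drawn every realization, so the
    realized ``a_i`` values trace out the whole Beta distribution and records
    can be binned by efficiency downstream.  With
    ``redraw_efficiencies=False`` a single vector drawn once is reused.
    """
    if rng is None:
        rng = np.random.default_rng(entry.seed_seq)
    I = entry.richness
    n = n_realizations
    eff = np.empty((n, I))
    W = np.empty((n, I))
    Y = np.empty((n, I))
    depths = np.empty(n, dtype=np.int64)
    degen = np.zeros(n, dtype=bool)

    fixed_eff = None
    if not redraw_efficiencies:
        fixed_eff = draw_efficiencies(entry.gamma, I, rng)
    weights = np.asarray(entry.weights, dtype=float) if entry.weights else None
    if weights is not None:
        lam = entry.lambda_level * weights / weights.mean()
    else:
        lam = np.full(I, entry.lambda_level)

    for r in range(n):
        a = fixed_eff if fixed_eff is not None else draw_efficiencies(entry.gamma, I, rng)
        w = rng.poisson(lam * protocol.volume_uL).astype(float)
        x1 = amplify_first_pcr(w, a, protocol.n_pcr1, rng)
        x2 = subsample_cleanup(x1, protocol.cleanup_fraction, rng)
        x3 = amplify_index_pcr(x2, protocol.n_pcr2, protocol.index_efficiency, rng)
        n_reads = protocol.depth_rule.draw(rng)
        try:
            p = compute_read_proportions(x3)
            y = draw_reads(p, n_reads, rng)
        except DegenerateReplicateError:
            y = np.zeros(I)
            degen[r] = True
        eff[r], W[r], Y[r], depths[r] = a, w, y, n_reads

    species = np.tile([f"sp{i + 1:03d}" for i in range(I)], n)
    return pd.DataFrame({
        "richness": I,
        "lambda_level": entry.lambda_level,
        "gamma": entry.gamma,
        "profile": entry.profile,
        "realization": np.repeat(np.arange(n), I),
        "species": species,
        "efficiency": eff.ravel(),
        "lam": np.tile(lam, n),
        "W": W.ravel(),
        "Y": Y.ravel(),
        "n_reads": np.repeat(depths, I),
        "degenerate": np.repeat(degen, I),
    })[RECORD_COLUMNS]


def run_grid(
    grid: ScenarioGrid,
    protocol: ProtocolParams | None = None,
    redraw_efficiencies: bool = True,
) -> pd.DataFrame:
    """Run every scenario of the grid and concatenate the record tables."""
    protocol = protocol or ProtocolParams()
    frames = [
        run_scenario(entry, protocol, grid.n_realizations,
                     redraw_efficiencies=redraw_efficiencies)
        for entry in grid.entries()
    ]
    return pd.concat(frames, ignore_index=True)


_SCENARIO_KEYS = ["richness", "lambda_level", "gamma", "profile"]


def _with_bins(records: pd.DataFrame, efficiency_bins) -> tuple[pd.DataFrame, list[str]]:
    keys = list(_SCENARIO_KEYS)
    if efficiency_bins is not None:
        records = records.copy()
        records["efficiency_bin"] = pd.cut(records["efficiency"], efficiency_bins)
        keys.append("efficiency_bin")
    return records, keys


def summarize_nondetection(
    records: pd.DataFrame,
    efficiency_bins=None,
) -> pd.DataFrame:
    """Tabulate the non-detection decomposition per scenario (and optional a-bin).

    Returns one row per group with counts and the fractions
    ``p_Y0`` = p(Y=0), ``p_W0`` = p(W=0) and ``p_Y0_given_Wpos`` =
    p(Y=0 | W>0).  Conditional fractions with an empty denominator are NaN
    (undefined), never 0.  On the tabulated counts the identity
    p(Y=0) = p(W=0) + p(Y=0|W>0) * (1 - p(W=0)) holds to rounding error.
    """
    if len(records) == 0:
        raise EmptyInputError("no scenario records to summarize")
    records, keys = _with_bins(records, efficiency_bins)
    df = records.assign(
        y0=records["Y"] == 0,
        w0=records["W"] == 0,
        wpos_y0=(records["W"] > 0) & (records["Y"] == 0),
        wpos=records["W"] > 0,
    )
    g = df.groupby(keys, observed=True)
    out = g.agg(
        n=("y0", "size"),
        n_Y0=("y0", "sum"),
        n_W0=("w0", "sum"),
        n_Wpos=("wpos", "sum"),
        n_Wpos_Y0=("wpos_y0", "sum"),
    ).reset_index()
    out["p_Y0"] = out["n_Y0"] / out["n"]
    out["p_W0"] = out["n_W0"] / out["n"]
    out["p_Y0_given_Wpos"] = np.where(
        out["n_Wpos"] > 0, out["n_Wpos_Y0"] / out["n_Wpos"].replace(0, np.nan), np.nan
    )
    return out


def summarize_reads(
    records: pd.DataFrame,
    efficiency_bins=None,
    by_species: bool = True,
) -> pd.DataFrame:
    """Mean/sd/CV of read counts and of relative abundance per group.

    Relative abundance uses each replicate's realized depth.  Standard
    deviations are population-style (ddof=0), so a single realization has
    sd = 0 rather than NaN.
    """
    if len(records) == 0:
        raise EmptyInputError("no scenario records to summarize")
    records, keys = _with_bins(records, efficiency_bins)
    if by_species and efficiency_bins is None:
        keys = keys + ["species"]
    df = records.assign(rel_abund=records["Y"] / records["n_reads"])
    g = df.groupby(keys, observed=True)

    def _std(x):
        return x.std(ddof=0)

    out = g.agg(
        n=("Y", "size"),
        mean_reads=("Y", "mean"),
        sd_reads=("Y", _std),
        mean_rel_abund=("rel_abund", "mean"),
        sd_rel_abund=("rel_abund", _std),
    ).reset_index()
    out["cv_reads"] = np.where(out["mean_reads"] > 0,
                               out["sd_reads"] / out["mean_reads"], np.nan)
    out["cv_rel_abund"] = np.where(out["mean_rel_abund"] > 0,
                                   out["sd_rel_abund"] / out["mean_rel_abund"], np.nan)
    return out
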