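"""Generative model of metabarcoding read counts for one technical replicate.

The chain of linked stochastic processes turns per-species template
concentrations into observed read counts:

1. template subsampling   W_i  ~ Poisson(lambda_i * V)
2. first (target) PCR     X1_i ~ Poisson(W_i * (1 + a_i)^Npcr1)
3. bead cleanup           X2_i ~ Binomial(X1_i, pi)
4. indexing PCR           X3_i ~ Poisson(X2_i * (1 + a_index)^Npcr2)
5. sequencing             Y    ~ Multinomial(N_reads, p),  p_i = X3_i / sum(X3)

``a_i`` is the species-specific per-cycle amplification efficiency
(``a_i = 1`` doubles the amplicon pool each cycle); the indexing PCR uses a
single shared efficiency because indexing primers anneal to the adapter, not
to species-specific sequence.  Zeros propagate structurally: a species whose
template count ``W_i`` is zero can never produce reads, so the chain
reproduces the zero-inflated, overdispersed (Poisson-stopped-sum) behaviour
of real amplicon data.

Counts with mean above :data:`EXACT_MEAN_LIMIT` are drawn from a rounded
Gaussian with matched mean and variance (clamped at zero); at that scale the
approximation error is negligible relative to any quantity of interest while
exact integer sampling would be pointless and overflow-prone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateReplicateError, InvalidParameterError

__all__ = [
    "CommunityProfile",
    "ProtocolParams",
    "ReadDepthRule",
    "ReplicateResult",
    "draw_template_counts",
    "amplify_first_pcr",
    "subsample_cleanup",
    "amplify_index_pcr",
    "compute_read_proportions",
    "draw_reads",
    "simulate_replicate",
]

#: Above this expected count, exact Poisson/binomial draws are replaced by a
#: rounded Gaussian with matched mean and variance.
EXACT_MEAN_LIMIT = 1.0e7

#: Above this amplicon count, read proportions are computed via shifted logs.
_LOG_PROPORTION_LIMIT = 1.0e15


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _poisson(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson draws, switching to a rounded Gaussian above EXACT_MEAN_LIMIT."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=float)
    small = mean <= EXACT_MEAN_LIMIT
    if small.any():
        out[small] = rng.poisson(mean[small])
    big = ~small
    if big.any():
        m = mean[big]
        out[big] = np.maximum(np.rint(rng.normal(m, np.sqrt(m))), 0.0)
    return out


def _binomial(n: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial draws with the same large-mean Gaussian contract as _poisson."""
    n = np.asarray(n, dtype=float)
    out = np.zeros(n.shape, dtype=float)
    small = n <= EXACT_MEAN_LIMIT
    if small.any():
        out[small] = rng.binomial(n[small].astype(np.int64), p)
    big = ~small
    if big.any():
        m = n[big] * p
        sd = np.sqrt(n[big] * p * (1.0 - p))
        draw = np.rint(rng.normal(m, sd))
        out[big] = np.clip(draw, 0.0, n[big])
    return out


@dataclass
class CommunityProfile:
    """Per-species template concentrations and amplification efficiencies.

    Parameters
    ----------
    species_ids
        Labels for the I species in the community.
    lambda_
        Template concentration per species, copies per microlitre (>= 0).
    efficiency
        Per-cycle amplification efficiency ``a_i`` in (0, 1]; 1 is a perfect
        doubling each cycle.
    """

    species_ids: list[str]
    lambda_: np.ndarray
    efficiency: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_ = np.asarray(self.lambda_, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        n = len(self.species_ids)
        if n < 1:
            raise InvalidParameterError("community must contain at least one species")
        if self.lambda_.shape != (n,) or self.efficiency.shape != (n,):
            raise InvalidParameterError(
                "species_ids, lambda_ and efficiency must have equal length"
            )
        if np.any(self.lambda_ < 0):
            raise InvalidParameterError("template concentrations must be >= 0")
        if np.any((self.efficiency <= 0) | (self.efficiency > 1)):
            raise InvalidParameterError("amplification efficiencies must lie in (0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclass(frozen=True)
class ReadDepthRule:
    """Discrete-uniform sequencing depth, inclusive on both bounds."""

    min_reads: int = 60_000
    max_reads: int = 140_000

    def __post_init__(self) -> None:
        if not (0 < self.min_reads <= self.max_reads):
            raise InvalidParameterError("require 0 < min_reads <= max_reads")

    def draw(self, rng: np.random.Generator | int | None = None) -> int:
        return int(_as_rng(rng).integers(self.min_reads, self.max_reads + 1))


@dataclass(frozen=True)
class ProtocolParams:
    """Laboratory-process constants of the two-step PCR library protocol.

    Defaults are the main-text setting: 1 uL template, 35 target-PCR cycles,
    10 indexing cycles, 20% of first-PCR product carried through cleanup,
    indexing efficiency 0.9, depth uniform on 60,000..140,000 reads.
    """

    volume_uL: float = 1.0
    n_pcr1: int = 35
    n_pcr2: int = 10
    cleanup_fraction: float = 0.20
    index_efficiency: float = 0.9
    depth_rule: ReadDepthRule = field(default_factory=ReadDepthRule)

    def __post_init__(self) -> None:
        if self.volume_uL <= 0:
            raise InvalidParameterError("template volume must be > 0")
        if self.n_pcr1 < 1 or self.n_pcr2 < 1:
            raise InvalidParameterError("PCR cycle counts must be positive integers")
        if not (0 < self.cleanup_fraction <= 1):
            raise InvalidParameterError("cleanup fraction must lie in (0, 1]")
        if not (0 < self.index_efficiency <= 1):
            raise InvalidParameterError("index efficiency must lie in (0, 1]")


@dataclass
class ReplicateResult:
    """Full latent chain W -> X1 -> X2 -> X3 -> p -> Y for one replicate.

    ``degenerate`` marks replicates whose amplicon pool died out entirely
    (all X3 = 0); they are recorded with all-zero reads rather than raised,
    so non-detection tallies include them.
    """

    replicate_id: str
    W: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    X3: np.ndarray
    p: np.ndarray
    n_reads: int
    Y: np.ndarray
    degenerate: bool = False


def draw_template_counts(
    community: CommunityProfile,
    volume_uL: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample template molecule counts W_i ~ Poisson(lambda_i * V).

    Each taxon is pipetted independently, so rare templates (small
    ``lambda * V``) are frequently absent from the reaction altogether.
    """
    if volume_uL <= 0:
        raise InvalidParameterError("template volume must be > 0")
    rng = _as_rng(rng)
    return rng.poisson(community.lambda_ * volume_uL).astype(float)


def amplify_first_pcr(
    W: np.ndarray,
    efficiency: np.ndarray,
    n_cycles: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Target-PCR amplicon counts X1_i ~ Poisson(W_i * (1 + a_i)^Npcr1).

    The Poisson of a geometric-growth mean given a Poisson template count is
    a Poisson-stopped sum (Neyman Type A), the source of the chain's
    overdispersion and zero inflation.
    """
    efficiency = np.asarray(efficiency, dtype=float)
    if np.any((efficiency <= 0) | (efficiency > 1)):
        raise InvalidParameterError("amplification efficiencies must lie in (0, 1]")
    if n_cycles < 1:
        raise InvalidParameterError("cycle count must be a positive integer")
    W = np.asarray(W, dtype=float)
    mean = W * (1.0 + efficiency) ** n_cycles
    return _poisson(mean, _as_rng(rng))


def subsample_cleanup(
    X1: np.ndarray,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Cleanup/carry-over subsample X2_i ~ Binomial(X1_i, pi)."""
    if not (0 < fraction <= 1):
        raise InvalidParameterError("cleanup fraction must lie in (0, 1]")
    X1 = np.asarray(X1, dtype=float)
    if fraction == 1.0:
        return X1.copy()
    return _binomial(X1, fraction, _as_rng(rng))


def amplify_index_pcr(
    X2: np.ndarray,
    n_cycles: int,
    index_efficiency: float = 0.9,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Indexing-PCR counts X3_i ~ Poisson(X2_i * (1 + e)^Npcr2), shared e.

    Indexing primers target the adapter sequence, so one efficiency applies
    to every species and this step is species-neutral in expectation.
    """
    if not (0 < index_efficiency <= 1):
        raise InvalidParameterError("index efficiency must lie in (0, 1]")
    if n_cycles < 1:
        raise InvalidParameterError("cycle count must be a positive integer")
    X2 = np.asarray(X2, dtype=float)
    mean = X2 * (1.0 + index_efficiency) ** n_cycles
    return _poisson(mean, _as_rng(rng))


def compute_read_proportions(X3: np.ndarray) -> np.ndarray:
    """Pre-sequencing read proportions p_i = X3_i / sum(X3).

    Raises
    ------
    DegenerateReplicateError
        If every amplicon count is zero (no proportions exist).
    """
    x = np.asarray(X3, dtype=float)
    if not np.any(x > 0):
        raise DegenerateReplicateError("all amplicon counts are zero")
    if x.max() > _LOG_PROPORTION_LIMIT:
        # p depends only on ratios; shifted logs avoid overflow at extreme counts
        with np.errstate(divide="ignore"):
            lg = np.log(x)
        w = np.exp(lg - lg.max())
        w[x == 0] = 0.0
        return w / w.sum()
    return x / x.sum()


def draw_reads(
    p: np.ndarray,
    n_reads: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Observed read counts Y ~ Multinomial(n_reads, p); sum(Y) == n_reads."""
    p = np.asarray(p, dtype=float)
    if n_reads < 0:
        raise InvalidParameterError("read depth must be >= 0")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("proportions must be non-negative and sum to 1")
    rng = _as_rng(rng)
    return rng.multinomial(int(n_reads), p / p.sum()).astype(float)


def simulate_replicate(
    community: CommunityProfile,
    protocol: ProtocolParams,
    rng: np.random.Generator | int | None = None,
    replicate_id: str = "rep1",
) -> ReplicateResult:
    """Run the full five-step chain for one technical replicate.

    The realized depth is drawn from the protocol's depth rule.  A replicate
    whose amplicon pool dies out (all X3 = 0) is returned with all-zero reads
    and ``degenerate=True`` instead of raising, so downstream non-detection
    tallies count it.
    """
    rng = _as_rng(rng)
    W = draw_template_counts(community, protocol.volume_uL, rng)
    X1 = amplify_first_pcr(W, community.efficiency, protocol.n_pcr1, rng)
    X2 = subsample_cleanup(X1, protocol.cleanup_fraction, rng)
    X3 = amplify_index_pcr(X2, protocol.n_pcr2, protocol.index_efficiency, rng)
    n_reads = protocol.depth_rule.draw(rng)
    try:
        p = compute_read_proportions(X3)
    except DegenerateReplicateError:
        zeros = np.zeros(community.n_species)
        return ReplicateResult(
            replicate_id, W, X1, X2, X3, zeros.copy(), n_reads, zeros.copy(),
            degenerate=True,
        )
    Y = draw_reads(p, n_reads, rng)
    return ReplicateResult(replicate_id, W, X1, X2, X3, p, n_reads, Y)
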