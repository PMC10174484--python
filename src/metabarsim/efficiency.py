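"""Mock-community calibration of relative amplification efficiencies.

Metabarcoding data are compositional, so absolute per-cycle efficiencies
``a_i`` are not identifiable from read counts alone; only efficiencies
relative to a reference species R are.  We work on the log scale,

    alpha_i = log((1 + a_i) / (1 + a_R))   per cycle,

so alpha_R = 0 by construction, alpha is negative for species that amplify
worse than the reference, and adding a common factor to every species'
per-cycle growth leaves alpha unchanged.  Given a mock community with known
input concentrations lambda_i, a moment estimator inverts the expected read
ratio E[Y_i / Y_R] ~ (lambda_i / lambda_R) * exp(Npcr * alpha_i):

    alpha_hat_i = (1 / Npcr) * [log(Y_i / Y_R) - log(lambda_i / lambda_R)]

per technical replicate, averaged over replicates.  Replicate-species
observations with zero reads carry no information about the ratio and are
dropped (no pseudocount — a pseudocount would bias alpha for exactly the
low-efficiency species of interest); an optional flag adds +0.5 to study
that sensitivity.  Uncertainty is the between-replicate standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "AVOGADRO",
    "EfficiencyEstimate",
    "copies_from_mass",
    "relative_efficiency",
    "efficiency_ratio",
    "estimate_relative_efficiencies",
    "classify_efficiency_groups",
]

AVOGADRO = 6.022e23
_MEAN_BP_MASS_G_PER_MOL = 650.0  # average mass of one double-stranded base pair
LOW_EFFICIENCY_THRESHOLD = -0.07


def copies_from_mass(concentration_ng_per_uL: float, amplicon_length_bp: int) -> float:
    """Convert a fluorometric dsDNA concentration (ng/uL) to copies/uL.

    copies/uL = conc * N_A / (length_bp * 650 g mol^-1 bp^-1 * 1e9 ng/g)
    """
    if amplicon_length_bp <= 0:
        raise InvalidParameterError("amplicon length must be a positive integer")
    if concentration_ng_per_uL < 0:
        raise InvalidParameterError("concentration must be >= 0")
    return (concentration_ng_per_uL * AVOGADRO
            / (amplicon_length_bp * _MEAN_BP_MASS_G_PER_MOL * 1e9))


def relative_efficiency(a_i: float, a_R: float) -> float:
    """Log-scale per-cycle efficiency of species i relative to reference R.

    alpha = log((1 + a_i) / (1 + a_R)); zero iff the efficiencies are equal,
    with sign(alpha) = sign(a_i - a_R).
    """
    for a in (a_i, a_R):
        if not (0 < a <= 1):
            raise InvalidParameterError("efficiencies must lie in (0, 1]")
    return float(np.log1p(a_i) - np.log1p(a_R))


def efficiency_ratio(a_i: float, a_R: float) -> float:
    """Raw efficiency ratio a_i / a_R (secondary, non-log scale)."""
    for a in (a_i, a_R):
        if not (0 < a <= 1):
            raise InvalidParameterError("efficiencies must lie in (0, 1]")
    return a_i / a_R


@dataclass
class EfficiencyEstimate:
    """Per-species relative-efficiency estimates from a mock community.

    ``table`` has columns species, alpha, se, n_observations, group; alpha of
    the reference species is exactly 0 and never-observed species carry NaN.
    """

    table: pd.DataFrame
    reference_species: str
    n_cycles: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _pivot_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Read table -> (replicate x species) count matrix; replicates keyed
    by (sample_id, replicate_id)."""
    return reads.pivot_table(
        index=["sample_id", "replicate_id"], columns="species_id",
        values="reads", aggfunc="sum", fill_value=0,
    )


def _choose_reference(mat: pd.DataFrame) -> str:
    """Species observed in every replicate with the highest mean read count."""
    always = mat.columns[(mat > 0).all(axis=0)]
    if len(always) == 0:
        raise InvalidParameterError(
            "no species is observed in every replicate; pass an explicit reference"
        )
    return str(mat[always].mean(axis=0).idxmax())


def estimate_relative_efficiencies(
    reads: pd.DataFrame,
    inputs: pd.DataFrame,
    n_cycles: int,
    reference: str = "auto",
    pseudocount: float = 0.0,
) -> EfficiencyEstimate:
    """Estimate per-species alpha from mock-community reads and known inputs.

    Parameters
    ----------
    reads
        Long-format read table (sample_id, replicate_id, species_id, reads).
    inputs
        Known inputs with columns ``species`` and either ``copies_per_uL`` or
        ``ng_per_uL`` + ``amplicon_length_bp`` (converted via
        :func:`copies_from_mass`).
    n_cycles
        First-PCR cycle count used to produce the reads.
    reference
        Reference species label, or ``"auto"`` to pick the species observed
        in every replicate with the highest mean read count.
    pseudocount
        Added to every retained count before taking logs; default 0 drops
        zero-read observations instead.
    """
    if n_cycles < 1:
        raise InvalidParameterError("cycle count must be a positive integer")
    inputs = inputs.copy()
    if "copies_per_uL" not in inputs.columns:
        if not {"ng_per_uL", "amplicon_length_bp"} <= set(inputs.columns):
            raise InvalidParameterError(
                "inputs need copies_per_uL or ng_per_uL + amplicon_length_bp"
            )
        inputs["copies_per_uL"] = [
            copies_from_mass(c, l)
            for c, l in zip(inputs["ng_per_uL"], inputs["amplicon_length_bp"])
        ]
    if np.any(inputs["copies_per_uL"] <= 0):
        raise InvalidParameterError("known input concentrations must be > 0")
    lam = inputs.set_index("species")["copies_per_uL"]

    mat = _pivot_reads(reads)
    known = [s for s in mat.columns if s in lam.index]
    missing = set(mat.columns) - set(lam.index)
    if missing:
        raise InvalidParameterError(
            f"species without known input concentrations: {sorted(missing)}"
        )
    mat = mat[known]

    if reference == "auto":
        reference = _choose_reference(mat)
    if reference not in mat.columns:
        raise InvalidParameterError(f"reference species {reference!r} not in read table")

    usable = mat[mat[reference] > 0]
    dropped = len(mat) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} replicate(s) where reference {reference!r} has zero reads",
            stacklevel=2,
        )
    if len(usable) == 0:
        raise EmptyInputError("reference species has zero reads in every replicate")

    counts = usable + pseudocount
    with np.errstate(divide="ignore"):
        log_ratio = np.log(counts.to_numpy()) - np.log(
            counts[reference].to_numpy()[:, None]
        )
    log_ratio[np.asarray(counts) <= 0] = np.nan  # zero reads: no observation
    log_lambda = np.log(lam[counts.columns].to_numpy() / lam[reference])
    per_replicate = (log_ratio - log_lambda[None, :]) / n_cycles

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        alpha = np.nanmean(per_replicate, axis=0)
        n_obs = np.sum(np.isfinite(per_replicate), axis=0)
        sd = np.nanstd(per_replicate, axis=0, ddof=1)
    se = np.where(n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
    alpha = np.where(n_obs > 0, alpha, np.nan)

    table = pd.DataFrame({
        "species": counts.columns,
        "alpha": alpha,
        "se": se,
        "n_observations": n_obs.astype(int),
    })
    # never-sequenced species from the known-input list still get a row
    unseen = [s for s in lam.index if s not in set(table["species"])]
    if unseen:
        table = pd.concat(
            [table, pd.DataFrame({"species": unseen, "alpha": np.nan,
                                  "se": np.nan, "n_observations": 0})],
            ignore_index=True,
        )
    table = table.sort_values("species", ignore_index=True)
    table["group"] = classify_efficiency_groups(table["alpha"])
    return EfficiencyEstimate(table, reference_species=str(reference),
                              n_cycles=int(n_cycles))


def classify_efficiency_groups(
    alpha: pd.Series | np.ndarray,
    threshold: float = LOW_EFFICIENCY_THRESHOLD,
) -> pd.Series:
    """Label species low (alpha strictly below threshold) or high; NaN alpha
    values are 'unclassified'."""
    alpha = pd.Series(np.asarray(alpha, dtype=float))
    labels = pd.Series(np.where(alpha < threshold, "low", "high"), index=alpha.index)
    labels[alpha.isna()] = "unclassified"
    return labels
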