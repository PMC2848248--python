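"""Differential expression, its variance, the parametric bootstrap and
trinary discretization.

Each stress experiment contributes a treatment and a control arm of log2-scale
replicate expression values.  Replicates are combined into a per-gene
differential expression (DE, the log2 treatment/control ratio) and a variance
estimate; a parametric bootstrap then draws Gaussian resamples around each
(DE, variance) pair, and every draw is discretized to down / no-regulation /
up states at the fixed log2 thresholds -1 and +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEProfile",
    "DiscreteDataset",
    "summarize",
    "summarize_experiments",
    "bootstrap",
    "discretize",
    "DOWN_THRESHOLD",
    "UP_THRESHOLD",
]

#: log2 DE below this value is called down-regulated.
DOWN_THRESHOLD = -1.0
#: log2 DE above this value is called up-regulated.
UP_THRESHOLD = 1.0


@dataclass
class DEProfile:
    """Per gene x experiment differential expression and variance estimate.

    ``de`` holds the log2 treatment/control ratio per gene and experiment,
    ``var`` the associated variance estimate (sum of the treatment and
    control log-expression variances; see :func:`summarize`).
    """

    de: pd.DataFrame
    var: pd.DataFrame
    variance_mode: str = "raw"

    def __post_init__(self) -> None:
        if self.de.shape != self.var.shape:
            raise ValueError("de and var must have identical shapes")
        if (self.var.to_numpy() < 0).any():
            raise ValueError("variance estimates must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.de.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.de.columns)


@dataclass
class DiscreteDataset:
    """Genes x experiments matrix over the states {-1, 0, +1}."""

    states: pd.DataFrame
    replicate_index: int = 0

    def __post_init__(self) -> None:
        values = self.states.to_numpy()
        if not np.isin(values, (-1, 0, 1)).all():
            raise ValueError("states must lie in {-1, 0, +1}")


def _arm_stats(matrix: pd.DataFrame, mode: str, allow_single: bool):
    """Mean and variance contribution of one replicate arm."""
    n = matrix.shape[1]
    if n < 2 and not (mode == "raw" and allow_single):
        raise ValueError(
            "at least 2 replicates per arm are required for the variance "
            "estimate (pass allow_single=True with variance_mode='raw' to "
            "accept a single replicate with zero variance contribution)"
        )
    mean = matrix.mean(axis=1)
    if n < 2:
        var = pd.Series(0.0, index=matrix.index)
    else:
        var = matrix.var(axis=1, ddof=1)
        if mode == "of_mean":
            var = var / n
    return mean, var


def summarize(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    variance_mode: str = "raw",
    allow_single: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Combine one experiment's replicate arms into per-gene (de, var).

    ``de`` is mean(treatment) - mean(control) on the log2 scale.  The
    variance estimate sums the two arms' log-expression variances; with
    ``variance_mode='raw'`` the sample variances are summed as-is, with
    ``'of_mean'`` each is scaled by its replicate number so the result is
    the variance of the DE estimator.

    Parameters
    ----------
    treatment, control
        Genes x replicates log2 expression matrices with identical,
        identically ordered gene indices.
    """
    if variance_mode not in ("raw", "of_mean"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if not treatment.index.equals(control.index):
        raise ValueError("treatment and control gene lists must match exactly")
    t_mean, t_var = _arm_stats(treatment, variance_mode, allow_single)
    c_mean, c_var = _arm_stats(control, variance_mode, allow_single)
    return t_mean - c_mean, t_var + c_var


def summarize_experiments(
    experiments: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    variance_mode: str = "raw",
    allow_single: bool = False,
) -> DEProfile:
    """Apply :func:`summarize` across experiments and assemble a DEProfile."""
    de_cols, var_cols = {}, {}
    for name, (treatment, control) in experiments.items():
        de_cols[name], var_cols[name] = summarize(
            treatment, control, variance_mode=variance_mode, allow_single=allow_single
        )
    de = pd.DataFrame(de_cols)
    var = pd.DataFrame(var_cols)
    return DEProfile(de=de, var=var, variance_mode=variance_mode)


def bootstrap(profile: DEProfile, n_samples: int, seed: int) -> np.ndarray:
    """Parametric bootstrap: Gaussian draws around each (de, var) entry.

    Returns an array of shape ``(n_samples, n_genes, n_experiments)``.
    Each bootstrap replicate is drawn from its own child RNG stream spawned
    deterministically from ``seed``, so replicate ``b`` is reproducible in
    isolation.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    de = profile.de.to_numpy(dtype=float)
    var = profile.var.to_numpy(dtype=float) + 0.0  # normalize IEEE -0.0
    if (var < 0).any():
        raise ValueError("negative variance")
    sd = np.sqrt(var)
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    out = np.empty((n_samples,) + de.shape)
    for b, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        out[b] = rng.normal(de, sd)
    return out


def discretize(x, down: float = DOWN_THRESHOLD, up: float = UP_THRESHOLD):
    """Trinary discretization of log2 DE values.

    x < down maps to -1 (down-regulated), x > up to +1 (up-regulated) and
    the closed middle band down <= x <= up to 0 (no regulation); the
    boundaries themselves are "no regulation".  Accepts scalars or arrays
    and preserves pandas labels.
    """
    if not down < up:
        raise ValueError("thresholds must satisfy down < up")
    arr = np.asarray(x, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN in input to discretize")
    states = np.where(arr < down, -1, np.where(arr > up, 1, 0))
    if np.isscalar(x) or np.ndim(x) == 0:
        return int(states)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(states, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(states, index=x.index)
    return states
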