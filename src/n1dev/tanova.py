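"""Topographic analysis of variance (TANOVA) and electrode-wise t-maps.

TANOVA asks whether the *configuration* of the scalp field differs between
conditions irrespective of its strength.  Per time sample, every subject's
condition map is GFP-normalized, condition grand-average maps are formed,
and a generalized dissimilarity

    s = sqrt( (1/K) * sum_c GFP(M_c - M_bar)^2 )

is computed, where ``M_c`` is condition *c*'s grand-average normalized map
and ``M_bar`` the mean of the ``M_c``.  The null distribution comes from
independently permuting condition labels within each subject (the paired
design's exchangeable unit); p-values use the add-one convention
``(1 + #{s_perm >= s_obs}) / (1 + B)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .erp import gfp


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Scale a scalp map (or channels x samples array) to unit GFP per sample.

    Maps with zero GFP are returned unchanged (nothing to normalize).
    """
    m = np.asarray(m, dtype=float)
    g = gfp(m)
    scale = np.where(g > 0, g, 1.0)
    return m / scale


def tanova_statistic(maps: np.ndarray) -> float:
    """Generalized topographic dissimilarity at one sample.

    Parameters
    ----------
    maps
        ``(n_subjects, n_conditions, n_channels)`` array of (normalized)
        maps.  The statistic is 0 iff all condition grand-average maps are
        identical.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected (n_subjects, n_conditions, n_channels)")
    n_sub, n_cond, _ = maps.shape
    if n_sub < 1 or n_cond < 2:
        raise ValueError("need at least 1 subject and 2 conditions")
    grand = maps.mean(axis=0)  # (K, C)
    centered = grand - grand.mean(axis=0, keepdims=True)
    g = gfp(centered.T)  # GFP of each condition's deviation map
    return float(np.sqrt(np.mean(g**2)))


@dataclass
class TanovaResult:
    """Per-sample observed dissimilarity and permutation p-values."""

    times_ms: np.ndarray
    statistic: np.ndarray
    p: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_ms": self.times_ms, "statistic": self.statistic, "p": self.p}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _perm_statistics(maps: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Statistics for a batch of within-subject label permutations.

    ``maps``: (n_sub, K, C, S); ``perm_idx``: (B, n_sub, K) condition
    re-orderings.  Returns (B, S).
    """
    n_sub, n_cond, n_ch, n_samp = maps.shape
    sub_idx = np.arange(n_sub)[None, :, None]
    shuffled = maps[sub_idx, perm_idx]  # (B, n_sub, K, C, S)
    grand = shuffled.mean(axis=1)  # (B, K, C, S)
    centered = grand - grand.mean(axis=1, keepdims=True)
    g2 = centered.var(axis=2)  # GFP^2 of each condition's deviation map: (B, K, S)
    return np.sqrt(g2.mean(axis=1))


def tanova_permutation_test(
    maps: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    normalize: bool = True,
    batch: int = 250,
) -> TanovaResult:
    """Permutation test of topographic condition differences per sample.

    Parameters
    ----------
    maps
        ``(n_subjects, n_conditions, n_channels, n_samples)`` condition maps
        per subject (e.g. ERPs restricted to the N1 window).
    n_permutations
        Random within-subject condition-label permutations (5000 gives a
        stable estimate at the 1% significance level).
    normalize
        GFP-normalize each subject-condition map per sample first, so the
        test is blind to field strength.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[..., None]
    if maps.ndim != 4:
        raise ValueError("expected (n_subjects, n_conditions, n_channels[, n_samples])")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n_sub, n_cond, n_ch, n_samp = maps.shape
    if normalize:
        g = maps.std(axis=2, keepdims=True, ddof=0)
        maps = maps / np.where(g > 0, g, 1.0)

    # observed statistic per sample
    identity = np.tile(np.arange(n_cond), (1, n_sub, 1))
    s_obs = _perm_statistics(maps, identity)[0]  # (S,)

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(n_samp, dtype=int)
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perm_idx = np.argsort(rng.random((b, n_sub, n_cond)), axis=2)
        s_perm = _perm_statistics(maps, perm_idx)  # (b, S)
        count_ge += (s_perm >= s_obs[None, :] - 1e-15).sum(axis=0)
        done += b
    p = (1.0 + count_ge) / (1.0 + n_permutations)
    times = np.arange(n_samp, dtype=float)
    return TanovaResult(
        times_ms=times, statistic=s_obs, p=p, n_permutations=n_permutations, seed=seed
    )


def electrode_t_map(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against zero per electrode on per-subject difference maps.

    Parameters
    ----------
    diffs
        ``(n_subjects, n_channels)`` window-averaged condition differences.

    Returns
    -------
    (t, p) arrays of length ``n_channels``.  Electrodes with zero variance
    get ``t = +/-inf`` (sign of the common difference; 0 -> t = 0) and
    ``p = 0`` (or 1 when the difference is exactly zero).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.empty_like(mean)
    p = np.empty_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sstats.t.sf(np.abs(t[ok]), df=n - 1)
    zero_var = ~ok
    with np.errstate(invalid="ignore"):
        t[zero_var] = np.where(mean[zero_var] == 0, 0.0, np.sign(mean[zero_var]) * np.inf)
    p[zero_var] = np.where(mean[zero_var] == 0, 1.0, 0.0)
    return t, p
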