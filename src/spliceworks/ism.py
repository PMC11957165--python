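"""In-silico saturation mutagenesis around splice sites.

For a window of positions around a scored splice site, every position is
substituted with each alternative base and the site is rescored; the
importance of a position is the reference score minus the mean score over
the three non-reference substitutions (a position the scorer ignores has
importance exactly 0). The published 4-base mean — which includes the
reference base and therefore scales importances by 3/4 — is available via
``include_ref_in_mean``. Per-(position, substitution) score decreases are
kept for DNA-logo style aggregation across many sites, and paired profiles
from two scorers are compared by Pearson correlation.

Scoring uses real sequence context (no N padding): the site must sit at
least ``cl/2`` bases from each end of the provided sequence. Ensemble
averaging of member scorers precedes the ISM differencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataprep import encode_sequence

logger = logging.getLogger(__name__)

__all__ = ["ISMProfile", "ism_importance", "aggregate_logo", "profile_correlation"]

BASES = "ACGT"
_CLASS_INDEX = {"acceptor": 1, "donor": 2}


@dataclass
class ISMProfile:
    """Importance profile around one splice site.

    ``decrease[p, b]`` is S_ref − S(mutate position p to base b); the
    reference base's own column is 0. ``importance`` has one entry per
    window position; ``offsets`` give positions relative to the site.
    """

    site_class: str
    site_pos: int
    offsets: np.ndarray
    importance: np.ndarray
    decrease: np.ndarray  # (window, 4)
    s_ref: float
    ref_bases: str


def _ensemble_site_scores(x: np.ndarray, scorers, out_index: int, class_index: int,
                          batch_size: int = 64) -> np.ndarray:
    scores = np.zeros(x.shape[0])
    for i in range(0, x.shape[0], batch_size):
        xb = x[i : i + batch_size]
        mean = None
        for scorer in scorers:
            p = scorer.score_batch(xb)
            mean = p if mean is None else mean + p
        scores[i : i + batch_size] = mean[:, out_index, class_index] / len(scorers)
    return scores


def ism_importance(
    scorers,
    sequence: str,
    site_pos: int,
    site_class: str,
    window: int = 81,
    include_ref_in_mean: bool = False,
    batch_size: int = 64,
) -> ISMProfile:
    """Mutate every base in a window around a site and rescore the site.

    ``window`` is the (odd) total number of positions centered on
    ``site_pos``. Raises if the site or the window lacks the scorer's
    required context within ``sequence``.
    """
    scorers = scorers if isinstance(scorers, (list, tuple)) else [scorers]
    cls = {s.cl for s in scorers}
    if len(cls) != 1:
        raise ValueError(f"ensemble members disagree on flank/cropping: {sorted(cls)}")
    cl = cls.pop()
    if site_class not in _CLASS_INDEX:
        raise ValueError(f"site_class must be 'donor' or 'acceptor', got {site_class!r}")
    if window % 2 != 1:
        raise ValueError(f"window must be odd, got {window}")
    half_win = window // 2
    radius = max(cl // 2, half_win)
    if site_pos - radius < 0 or site_pos + radius >= len(sequence):
        raise ValueError(
            f"site at {site_pos} needs {radius} nt of context on each side "
            f"within the sequence (length {len(sequence)})"
        )
    sub = sequence[site_pos - radius : site_pos + radius + 1].upper()
    out_index = radius - cl // 2  # site position in the scorer output
    class_index = _CLASS_INDEX[site_class]

    ref_x = encode_sequence(sub)
    s_ref = float(_ensemble_site_scores(ref_x[None], scorers, out_index, class_index)[0])

    offsets = np.arange(-half_win, half_win + 1)
    win_positions = offsets + radius  # indices into `sub`
    ref_bases = "".join(sub[p] for p in win_positions)

    # batch of mutated sequences: one per (position, alternative base)
    muts: list[np.ndarray] = []
    slots: list[tuple[int, int]] = []
    for wi, p in enumerate(win_positions):
        for bi, base in enumerate(BASES):
            if base == sub[p]:
                continue
            x = ref_x.copy()
            x[p] = 0.0
            x[p, bi] = 1.0
            muts.append(x)
            slots.append((wi, bi))
    alt_scores = _ensemble_site_scores(np.stack(muts), scorers, out_index, class_index, batch_size)

    decrease = np.zeros((window, 4))
    for (wi, bi), s_alt in zip(slots, alt_scores):
        decrease[wi, bi] = s_ref - s_alt
    denom = 4.0 if include_ref_in_mean else 3.0
    importance = decrease.sum(axis=1) / denom
    return ISMProfile(
        site_class=site_class, site_pos=site_pos, offsets=offsets,
        importance=importance, decrease=decrease, s_ref=s_ref, ref_bases=ref_bases,
    )


def aggregate_logo(profiles: list[ISMProfile]) -> np.ndarray:
    """Elementwise mean of per-site decrease matrices (a PWM-style logo).

    All profiles must share window geometry and site class.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    first = profiles[0]
    for p in profiles[1:]:
        if p.decrease.shape != first.decrease.shape or p.site_class != first.site_class:
            raise ValueError("profiles with mixed geometries or site classes cannot be aggregated")
    return np.mean([p.decrease for p in profiles], axis=0)


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson r between two equal-length importance profiles.

    Accepts ISMProfile objects or plain arrays; returns NaN (reported as
    missing) when either profile has zero variance.
    """
    a = profile_a.importance if isinstance(profile_a, ISMProfile) else np.asarray(profile_a, dtype=float)
    b = profile_b.importance if isinstance(profile_b, ISMProfile) else np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profiles differ in length: {a.shape} vs {b.shape}")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("zero-variance profile; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
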