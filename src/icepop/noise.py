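"""Dual-reporter intrinsic/extrinsic noise decomposition with bootstrap.

Two identical promoter copies driving distinguishable reporters (eGFP and
eCherry) in the same cell separate expression variability into an intrinsic
part — uncorrelated between the two reporters — and an extrinsic part shared
by both.  With ``g`` and ``c`` the normalized per-cell reporter values and
angled brackets denoting population means, the moment definitions are

    eta_int^2 = <(g - c)^2> / (2 <g><c>)
    eta_ext^2 = (<g c> - <g><c>) / (<g><c>)
    eta_tot^2 = ((<g^2> + <c^2>)/2 - <g><c>) / (<g><c>)

and the identity ``eta_tot^2 = eta_int^2 + eta_ext^2`` holds exactly for any
sample.  The sample ``eta_ext^2`` can be negative at small n; it is kept
signed so the identity stays exact, and ``eta_ext`` is reported as
``sign(eta_ext^2) * sqrt(|eta_ext^2|)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseEstimate",
    "scale_and_normalize",
    "select_active",
    "noise_decomposition",
    "bootstrap_noise",
]


@dataclass
class NoiseEstimate:
    """Point estimates (and optionally bootstrap summaries) of the three
    noise components.

    ``eta_ext_sq_signed`` preserves the raw (possibly negative) extrinsic
    variance ratio so that ``eta_tot**2 == eta_int**2 + eta_ext_sq_signed``
    to machine precision.
    """

    eta_int: float
    eta_ext: float
    eta_tot: float
    eta_ext_sq_signed: float
    n_cells: int
    boot_mean: dict[str, float] | None = None
    boot_sd: dict[str, float] | None = None
    n_boot: int = 0
    n_redrawn: int = 0
    seed: int | None = None

    @property
    def eta_ext_negative(self) -> bool:
        return self.eta_ext_sq_signed < 0


def _as_pair(g, c) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if g.size != c.size:
        raise ValueError(f"paired channels differ in length: {g.size} vs {c.size}")
    return g, c


def scale_and_normalize(
    raw_g, raw_c, background_g: float = 0.0, background_c: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract each channel and rescale it to [0, 100].

    Per channel: subtract the image background, floor at zero, divide by the
    population maximum and multiply by 100, so the brightest cell of each
    channel maps to exactly 100.  Channels are normalized independently,
    which makes the two reporters comparable despite different detector
    gains.

    Raises
    ------
    ValueError
        If a channel is all zero after background subtraction (no signal to
        normalize against).
    """
    g, c = _as_pair(raw_g, raw_c)
    out = []
    for name, raw, bg in (("g", g, background_g), ("c", c, background_c)):
        shifted = np.maximum(raw - bg, 0.0)
        top = shifted.max() if shifted.size else 0.0
        if top <= 0:
            raise ValueError(f"channel {name!r} has no signal after background subtraction")
        out.append(100.0 * shifted / top)
    return out[0], out[1]


def select_active(
    g,
    c,
    breakpoint_g: float,
    breakpoint_c: float,
    saturated=None,
    exclude_saturated: bool = True,
    mode: str = "union",
) -> tuple[np.ndarray, np.ndarray]:
    """Gate the paired sample to the activated subpopulation.

    A cell is retained when its value exceeds the breakpoint of the g-channel
    *or* of the c-channel cumulative curve (``mode="intersection"`` requires
    both).  Breakpoints are given as percentiles (percent of the respective
    channel's distribution).  Cells flagged as camera-saturated can be
    excluded before gating.

    Raises
    ------
    ValueError
        If fewer than 2 cells survive the gate (noise undefined).
    """
    g, c = _as_pair(g, c)
    if not (0.0 <= breakpoint_g <= 100.0 and 0.0 <= breakpoint_c <= 100.0):
        raise ValueError("breakpoints must be percentiles in [0, 100]")
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")

    keep = np.ones(g.size, dtype=bool)
    if saturated is not None and exclude_saturated:
        keep &= ~np.asarray(saturated, dtype=bool)

    thr_g = np.percentile(g[keep], breakpoint_g) if breakpoint_g > 0 else -np.inf
    thr_c = np.percentile(c[keep], breakpoint_c) if breakpoint_c > 0 else -np.inf
    above_g = g > thr_g
    above_c = c > thr_c
    gate = (above_g | above_c) if mode == "union" else (above_g & above_c)
    gate &= keep

    if gate.sum() < 2:
        raise ValueError(
            f"only {int(gate.sum())} cells above the breakpoints; "
            "noise decomposition needs at least 2"
        )
    return g[gate], c[gate]


def noise_decomposition(g, c, seed: int | None = None) -> NoiseEstimate:
    """Compute intrinsic, extrinsic and total noise from paired reporters.

    Raises
    ------
    ValueError
        If fewer than 2 cells are given or either channel has zero mean.
    """
    g, c = _as_pair(g, c)
    if g.size < 2:
        raise ValueError(f"noise decomposition needs >= 2 cells, got {g.size}")
    mg = float(np.mean(g))
    mc = float(np.mean(c))
    if mg <= 0 or mc <= 0:
        raise ValueError(f"channel means must be positive, got <g>={mg}, <c>={mc}")

    denom = mg * mc
    eta_int_sq = float(np.mean((g - c) ** 2)) / (2.0 * denom)
    eta_ext_sq = (float(np.mean(g * c)) - denom) / denom
    eta_tot_sq = ((float(np.mean(g**2)) + float(np.mean(c**2))) / 2.0 - denom) / denom

    return NoiseEstimate(
        eta_int=math.sqrt(eta_int_sq),
        eta_ext=math.copysign(math.sqrt(abs(eta_ext_sq)), eta_ext_sq),
        eta_tot=math.sqrt(max(eta_tot_sq, 0.0)),
        eta_ext_sq_signed=eta_ext_sq,
        n_cells=g.size,
        seed=seed,
    )


_COMPONENTS = ("eta_int", "eta_ext", "eta_tot")


def bootstrap_noise(
    g, c, n_boot: int = 1000, seed: int = 0, max_redraws: int = 100
) -> NoiseEstimate:
    """Noise decomposition with bootstrap means and SDs over cell resamples.

    Cells are resampled with replacement ``n_boot`` times; the decomposition
    is computed on every resample and each component is summarized by its
    mean and SD across resamples.  A resample in which a channel mean is not
    positive is redrawn (bounded by ``max_redraws`` in total) and counted in
    ``n_redrawn``.  Deterministic for a fixed seed.
    """
    g, c = _as_pair(g, c)
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    point = noise_decomposition(g, c, seed=seed)

    rng = np.random.default_rng(seed)
    n = g.size
    draws = {k: np.empty(n_boot) for k in _COMPONENTS}
    redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            gb, cb = g[idx], c[idx]
            if np.mean(gb) > 0 and np.mean(cb) > 0:
                break
            redrawn += 1
        else:
            raise RuntimeError(
                f"bootstrap resample kept a zero-mean channel after "
                f"{max_redraws} redraws"
            )
        est = noise_decomposition(gb, cb)
        for k in _COMPONENTS:
            draws[k][b] = getattr(est, k)

    point.boot_mean = {k: float(np.mean(v)) for k, v in draws.items()}
    point.boot_sd = {k: float(np.std(v, ddof=1)) if n_boot > 1 else 0.0 for k, v in draws.items()}
    point.n_boot = n_boot
    point.n_redrawn = redrawn
    return point
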