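"""Generative model of bistable mobile-element activation in a clonal population.

The model captures how cell-to-cell variability in a global sigma factor
(RpoS) gates a low-frequency ON decision.  Each cell draws a sigma-factor
level ``R`` from a truncated normal distribution; cells above a threshold
``theta`` are *permissive*, and a permissive cell switches ON with
probability ``p_act`` (the unidentified co-regulator, "factor X").  Reporter
fluorescence is the ON/OFF promoter output multiplied by shared (extrinsic)
and channel-specific (intrinsic) lognormal noise factors, plus additive
camera background, clipped to the sensor range.

The expected ON fraction is therefore ``p_act * Phi((c*mu_R - theta)/sigma_R)``
with ``Phi`` the standard normal CDF and ``c`` the gene copy number — the
activated subpopulation is an emergent upper-tail probability of the
sigma-factor distribution, which is the point of the model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationParams",
    "SimulatedPopulation",
    "DualReporterSample",
    "TransferAssay",
    "simulate_population",
    "simulate_dual_reporter",
    "render_images",
    "simulate_transfer_assay",
    "preset",
    "PRESETS",
]

#: z-score whose upper-tail probability is 3% — the wild-type activation level
Z_WILDTYPE = 1.881
#: z-score whose upper-tail probability is 18% — the double-copy rpoS level
Z_RPOS_PLUS = 0.915


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of the threshold-activation model.

    Parameters
    ----------
    n_cells
        Number of cells to simulate.
    mu_R, sigma_R
        Mean and SD of the per-cell sigma-factor level, in arbitrary
        fluorescence units (AFU).  The population distribution is normal,
        truncated at zero.
    copy_number
        Gene copy number of the sigma factor; multiplies ``mu_R`` only.
    theta
        Activation threshold on the sigma-factor level (AFU).
    p_act
        Probability that a permissive cell (``R >= theta``) actually
        switches ON ("factor X").
    basal, amplitude
        OFF-state reporter output and the ON-state increment (AFU).
    sigma_E, sigma_I
        Lognormal shape parameters of the shared extrinsic factor and of
        each channel's independent intrinsic factor.  Both factors have
        unit mean.
    background_mean, background_sd
        Additive camera background (gray levels).
    bit_depth
        Camera bit depth; pixel values are clipped to ``[0, 2**bit_depth - 1]``.
    seed
        RNG seed; identical seeds give byte-identical output.
    """

    n_cells: int = 10_000
    mu_R: float = 50.0
    sigma_R: float = 10.0
    copy_number: int = 1
    theta: float = 50.0 + Z_WILDTYPE * 10.0
    p_act: float = 1.0
    basal: float = 5.0
    amplitude: float = 195.0
    sigma_E: float = 0.2
    sigma_I: float = 0.2
    background_mean: float = 10.0
    background_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, f"n_cells must be >= 1, got {self.n_cells}")
        _require(self.sigma_R >= 0, f"sigma_R must be >= 0, got {self.sigma_R}")
        _require(0.0 <= self.p_act <= 1.0, f"p_act must be in [0, 1], got {self.p_act}")
        _require(self.sigma_E >= 0, f"sigma_E must be >= 0, got {self.sigma_E}")
        _require(self.sigma_I >= 0, f"sigma_I must be >= 0, got {self.sigma_I}")
        _require(self.copy_number >= 1, f"copy_number must be >= 1, got {self.copy_number}")
        _require(self.bit_depth in (8, 16), f"bit_depth must be 8 or 16, got {self.bit_depth}")
        _require(self.basal >= 0, f"basal must be >= 0, got {self.basal}")
        _require(self.amplitude >= 0, f"amplitude must be >= 0, got {self.amplitude}")
        _require(self.background_sd >= 0, f"background_sd must be >= 0, got {self.background_sd}")

    @property
    def sensor_max(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def expected_on_fraction(self) -> float:
        """p_act * P(R >= theta), ignoring the (negligible) truncation at 0."""
        if self.sigma_R == 0:
            tail = 1.0 if self.copy_number * self.mu_R >= self.theta else 0.0
        else:
            z = (self.theta - self.copy_number * self.mu_R) / self.sigma_R
            tail = stats.norm.sf(z)
        return self.p_act * tail

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Named parameter sets for the two headline conditions: the wild type
#: activates ~3% of cells; doubling the sigma-factor copy number doubles the
#: mean level so that ~the whole population clears the wild-type threshold,
#: while ``rpos_plus`` keeps copy number 1 and lowers the threshold margin to
#: the z-score whose tail is 18%.
PRESETS: dict[str, dict] = {
    "wildtype": {},
    "rpos_double": {"copy_number": 2},
    "rpos_plus": {"theta": 50.0 + Z_RPOS_PLUS * 10.0},
}


def preset(name: str, **overrides) -> SimulationParams:
    """Return a named :class:`SimulationParams` preset, with overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return SimulationParams(**{**base, **overrides})


@dataclass
class SimulatedPopulation:
    """Per-cell ground truth and observed channel values for one simulation."""

    params: SimulationParams
    cell_id: np.ndarray        # int
    R: np.ndarray              # sigma-factor level, AFU
    permissive: np.ndarray     # bool, R >= theta
    active: np.ndarray         # bool, permissive AND factor-X draw
    E: np.ndarray              # shared extrinsic factor, unit mean
    signal_g: np.ndarray       # noiseless+noise channel signal before camera
    signal_c: np.ndarray
    agv_g: np.ndarray          # observed gray values, clipped to sensor range
    agv_c: np.ndarray
    saturated_g: np.ndarray    # bool, clipped at sensor max
    saturated_c: np.ndarray

    def __len__(self) -> int:
        return len(self.cell_id)

    @property
    def active_fraction(self) -> float:
        return float(np.mean(self.active))

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-cell table, one row per cell and channel."""
        n = len(self)
        rows = []
        for channel, agv, sat in (
            ("g", self.agv_g, self.saturated_g),
            ("c", self.agv_c, self.saturated_c),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": self.cell_id,
                        "image_id": np.zeros(n, dtype=int),
                        "replicate": np.zeros(n, dtype=int),
                        "channel": channel,
                        "raw_agv": agv,
                        "saturated": sat,
                        "true_R": self.R,
                        "true_active": self.active,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _lognormal_unit_mean(rng: np.random.Generator, shape: float, size: int) -> np.ndarray:
    """LogNormal(-shape^2/2, shape): multiplicative factor with mean exactly 1."""
    if shape == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * shape**2, sigma=shape, size=size)


def simulate_population(params: SimulationParams) -> SimulatedPopulation:
    """Draw a clonal population under the threshold-activation model.

    The sigma-factor level is Normal(copy_number * mu_R, sigma_R) truncated
    at zero; activation requires both clearing ``theta`` and an independent
    Bernoulli(``p_act``) success.  Observed channel values are
    ``E * eps * (basal + amplitude * active) + background``, clipped to the
    sensor range.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    mean_R = params.copy_number * params.mu_R

    if params.sigma_R == 0:
        R = np.full(n, float(mean_R))
    else:
        a = (0.0 - mean_R) / params.sigma_R  # truncation at zero, in z units
        R = stats.truncnorm.rvs(
            a, np.inf, loc=mean_R, scale=params.sigma_R, size=n, random_state=rng
        )

    permissive = R >= params.theta
    active = permissive & (rng.random(n) < params.p_act)

    E = _lognormal_unit_mean(rng, params.sigma_E, n)
    eps_g = _lognormal_unit_mean(rng, params.sigma_I, n)
    eps_c = _lognormal_unit_mean(rng, params.sigma_I, n)

    expression = params.basal + params.amplitude * active.astype(float)
    signal_g = E * eps_g * expression
    signal_c = E * eps_c * expression

    bg_g = rng.normal(params.background_mean, params.background_sd, n)
    bg_c = rng.normal(params.background_mean, params.background_sd, n)

    raw_g = signal_g + bg_g
    raw_c = signal_c + bg_c
    smax = params.sensor_max
    agv_g = np.clip(raw_g, 0.0, smax)
    agv_c = np.clip(raw_c, 0.0, smax)

    return SimulatedPopulation(
        params=params,
        cell_id=np.arange(n),
        R=R,
        permissive=permissive,
        active=active,
        E=E,
        signal_g=signal_g,
        signal_c=signal_c,
        agv_g=agv_g,
        agv_c=agv_c,
        saturated_g=raw_g >= smax,
        saturated_c=raw_c >= smax,
    )


@dataclass
class DualReporterSample:
    """Paired two-color reporter values with analytically known noise truths.

    ``g = E*a`` and ``c = E*b`` where ``E`` is the shared extrinsic factor and
    ``a``, ``b`` are independent intrinsic factors, all unit-mean lognormal.
    The closed forms follow from lognormal moments:

    * ``eta_ext_true  = CV_E          = sqrt(exp(sigma_E^2) - 1)``
    * ``eta_int_true  = CV_a * sqrt(1 + CV_E^2)``
    * ``eta_tot_true  = sqrt(eta_int_true^2 + eta_ext_true^2)``
    """

    g: np.ndarray
    c: np.ndarray
    sigma_E: float
    sigma_I: float
    eta_ext_true: float
    eta_int_true: float

    @property
    def eta_tot_true(self) -> float:
        return math.hypot(self.eta_int_true, self.eta_ext_true)


def simulate_dual_reporter(
    n: int, sigma_E: float, sigma_I: float, seed: int = 0
) -> DualReporterSample:
    """Generate paired reporter values sharing an extrinsic factor.

    Raises
    ------
    ValueError
        If ``n < 2`` (sample moments undefined) or a shape is negative.
    """
    _require(n >= 2, f"n must be >= 2 for defined sample moments, got {n}")
    _require(sigma_E >= 0, f"sigma_E must be >= 0, got {sigma_E}")
    _require(sigma_I >= 0, f"sigma_I must be >= 0, got {sigma_I}")

    rng = np.random.default_rng(seed)
    E = _lognormal_unit_mean(rng, sigma_E, n)
    a = _lognormal_unit_mean(rng, sigma_I, n)
    b = _lognormal_unit_mean(rng, sigma_I, n)

    cv_E = math.sqrt(math.exp(sigma_E**2) - 1.0)
    cv_a = math.sqrt(math.exp(sigma_I**2) - 1.0)
    return DualReporterSample(
        g=E * a,
        c=E * b,
        sigma_E=sigma_E,
        sigma_I=sigma_I,
        eta_ext_true=cv_E,
        eta_int_true=cv_a * math.sqrt(1.0 + cv_E**2),
    )


def render_images(
    values: np.ndarray,
    image_shape: tuple[int, int] = (512, 512),
    cells_per_image: int = 50,
    cell_radius_range: tuple[float, float] = (4.0, 8.0),
    background_mean: float = 10.0,
    background_sd: float = 2.0,
    bit_depth: int = 8,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame]:
    """Render per-cell intensities as non-overlapping ellipses on noisy images.

    Each cell becomes an ellipse whose interior is filled with its channel
    value; background pixels are Normal(background_mean, background_sd);
    everything is clipped to the sensor range.  Returns the images, matching
    ground-truth label masks (cell ``k`` of an image carries label ``k+1``)
    and a table mapping (image_id, label) to the input value.

    Raises
    ------
    RuntimeError
        If non-overlapping placement fails after ``max_tries`` attempts,
        reporting how many cells could be placed.
    """
    from skimage.draw import ellipse as draw_ellipse

    values = np.asarray(values, dtype=float)
    _require(bit_depth in (8, 16), f"bit_depth must be 8 or 16, got {bit_depth}")
    rng = np.random.default_rng(seed)
    smax = 2**bit_depth - 1
    h, w = image_shape
    rmin, rmax = cell_radius_range
    _require(0 < rmin <= rmax, "cell_radius_range must satisfy 0 < rmin <= rmax")
    _require(
        2 * rmax < min(h, w), "image too small for the requested cell radius range"
    )

    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    records: list[dict] = []

    for start in range(0, len(values), cells_per_image) if len(values) else [0]:
        chunk = values[start : start + cells_per_image]
        image = rng.normal(background_mean, background_sd, size=(h, w))
        mask = np.zeros((h, w), dtype=np.int32)
        image_id = len(images)

        for k, value in enumerate(chunk):
            placed = False
            for _ in range(max_tries):
                ry = rng.uniform(rmin, rmax)
                rx = rng.uniform(rmin, rmax)
                cy = rng.uniform(ry + 1, h - ry - 1)
                cx = rng.uniform(rx + 1, w - rx - 1)
                rot = rng.uniform(0, np.pi)
                rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
                if rr.size and not mask[rr, cc].any():
                    image[rr, cc] = value
                    mask[rr, cc] = k + 1
                    records.append(
                        {
                            "image_id": image_id,
                            "label": k + 1,
                            "true_value": float(value),
                            "area": int(rr.size),
                        }
                    )
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place cell {start + k} without overlap after "
                    f"{max_tries} tries; {k} of {len(chunk)} cells placed on "
                    f"image {image_id}"
                )

        dtype = np.uint8 if bit_depth == 8 else np.uint16
        images.append(np.clip(np.round(image), 0, smax).astype(dtype))
        masks.append(mask)

    truth = pd.DataFrame(records, columns=["image_id", "label", "true_value", "area"])
    return images, masks, truth


@dataclass
class TransferAssay:
    """Outcome of one simulated conjugation (filter-mating) assay."""

    n_donors: int
    transconjugants: int

    @property
    def frequency(self) -> float:
        return self.transconjugants / self.n_donors


def simulate_transfer_assay(
    n_donors: int,
    activation_fraction: float,
    p_transfer_given_active: float,
    seed: int = 0,
) -> TransferAssay:
    """Binomial model of transconjugant counts per donor population.

    Only activated donors can transfer, so the per-donor success probability
    is ``activation_fraction * p_transfer_given_active``.
    """
    _require(n_donors >= 1, f"n_donors must be >= 1, got {n_donors}")
    _require(
        0.0 <= activation_fraction <= 1.0,
        f"activation_fraction must be in [0, 1], got {activation_fraction}",
    )
    _require(
        0.0 <= p_transfer_given_active <= 1.0,
        f"p_transfer_given_active must be in [0, 1], got {p_transfer_given_active}",
    )
    rng = np.random.default_rng(seed)
    p = activation_fraction * p_transfer_given_active
    return TransferAssay(
        n_donors=n_donors, transconjugants=int(rng.binomial(n_donors, p))
    )
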