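"""Tissue dielectric dispersion: 4-pole Cole-Cole spectra, Debye lymph-node
curves, the ±5% physiological-variation bounds, and the voxel-wise mapping
from MRI intensity to relative permittivity and conductivity.

The complex relative permittivity of a tissue is modelled as

    eps(w) = eps_inf + sum_n  d_eps_n / (1 + (j w tau_n)^(1 - alpha_n))
             + sigma_s / (j w eps0)

with four relaxation poles n = 1..4 (Debye is the one-pole alpha = 0
special case).  At a given angular frequency w the real part is the
relative permittivity and the total conductivity is sigma = -w eps0 Im eps,
which folds the static term sigma_s together with the dispersive losses.

Physiological variability of bone, fat and muscle is represented by bound
curves at ±``fraction`` (default 5%) of the nominal *property values* —
output-space scaling, so upper/nominal is exactly 1 + fraction at every
frequency and for both properties.  Skin carries no bounds.  The mixed
tissue, being a composite of adipose, connective, muscle and small bone,
spans from the fat lower bound to the muscle upper bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import labels as L
from .errors import ConfigError
from .io_volumes import VoxelVolume

logger = logging.getLogger(__name__)

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: supported frequency band, Hz (inclusive on both ends)
FREQUENCY_BAND_HZ = (1e9, 1e10)

#: default physiological variation applied to bone, fat and muscle
DEFAULT_BOUND_FRACTION = 0.05


def check_frequency(frequency_hz: float) -> float:
    f = float(frequency_hz)
    lo, hi = FREQUENCY_BAND_HZ
    if not lo <= f <= hi:
        raise ConfigError(
            f"frequency {f / 1e9:g} GHz outside the supported band "
            f"[{lo / 1e9:g}, {hi / 1e9:g}] GHz")
    return f


@dataclass(frozen=True)
class ColeColeParams:
    """Parameters of one 4-pole Cole-Cole spectrum.

    eps_inf : high-frequency relative permittivity (>= 1, unitless)
    poles : four (delta_eps, tau_s, alpha) triples; delta_eps unitless,
        tau in seconds, alpha in [0, 1)
    sigma_s : static conductivity, S/m
    """

    eps_inf: float
    poles: tuple[tuple[float, float, float], ...]
    sigma_s: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ConfigError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.sigma_s < 0:
            raise ConfigError(f"sigma_s must be >= 0, got {self.sigma_s}")
        if len(self.poles) != 4:
            raise ConfigError(f"expected 4 poles, got {len(self.poles)}")
        for n, (de, tau, alpha) in enumerate(self.poles, start=1):
            if de < 0:
                raise ConfigError(f"pole {n}: delta_eps must be >= 0, got {de}")
            if de > 0 and tau <= 0:
                raise ConfigError(f"pole {n}: tau must be > 0 when delta_eps > 0")
            if not 0 <= alpha < 1:
                raise ConfigError(f"pole {n}: alpha must be in [0, 1), got {alpha}")


@dataclass(frozen=True)
class DebyeParams:
    """Single-pole Debye spectrum (Cole-Cole with alpha = 0)."""

    eps_inf: float
    delta_eps: float
    tau: float
    sigma_s: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ConfigError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps < 0:
            raise ConfigError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if self.delta_eps > 0 and self.tau <= 0:
            raise ConfigError("tau must be > 0 when delta_eps > 0")
        if self.sigma_s < 0:
            raise ConfigError(f"sigma_s must be >= 0, got {self.sigma_s}")


def complex_permittivity(params: ColeColeParams, frequency_hz) -> np.ndarray:
    """Complex relative permittivity eps(w) at one or many frequencies."""
    f = np.asarray(frequency_hz, dtype=np.float64)
    if np.any(f <= 0):
        raise ConfigError("frequency must be > 0")
    w = 2.0 * np.pi * f
    eps = np.full_like(w, params.eps_inf, dtype=np.complex128)
    for de, tau, alpha in params.poles:
        if de > 0:
            eps = eps + de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    if params.sigma_s > 0:
        eps = eps + params.sigma_s / (1j * w * EPS0)
    return eps


def evaluate_cole_cole(params: ColeColeParams, frequency_hz):
    """(relative permittivity, total conductivity S/m) at the frequency.

    Accepts a scalar or an array of frequencies; returns matching shapes.
    """
    eps = complex_permittivity(params, frequency_hz)
    w = 2.0 * np.pi * np.asarray(frequency_hz, dtype=np.float64)
    eps_r = eps.real
    sigma = -w * EPS0 * eps.imag
    if np.isscalar(frequency_hz) or np.ndim(frequency_hz) == 0:
        return float(eps_r), float(sigma)
    return eps_r, sigma


def debye_to_cole_cole(d: DebyeParams) -> ColeColeParams:
    """Embed a Debye spectrum as pole 1 of a 4-pole Cole-Cole model;
    poles 2-4 are null."""
    tau1 = d.tau if d.delta_eps > 0 else 1.0  # tau irrelevant for a null pole
    return ColeColeParams(
        eps_inf=d.eps_inf,
        poles=((d.delta_eps, tau1, 0.0), (0.0, 1.0, 0.0), (0.0, 1.0, 0.0), (0.0, 1.0, 0.0)),
        sigma_s=d.sigma_s,
    )


def build_bounds(params: ColeColeParams, frequency_hz,
                 fraction: float = DEFAULT_BOUND_FRACTION):
    """Lower/upper property spectra at ±fraction of the nominal values.

    Returns ((eps_lo, sigma_lo), (eps_hi, sigma_hi)) evaluated at the given
    frequency (scalar or array).  The scaling is applied to the evaluated
    property values, so upper/nominal is exactly ``1 + fraction``.
    """
    if not 0 <= fraction <= 0.5:
        raise ConfigError(f"bound fraction must be in [0, 0.5], got {fraction}")
    eps_r, sigma = evaluate_cole_cole(params, frequency_hz)
    lower = ((1.0 - fraction) * np.asarray(eps_r), (1.0 - fraction) * np.asarray(sigma))
    upper = ((1.0 + fraction) * np.asarray(eps_r), (1.0 + fraction) * np.asarray(sigma))
    if np.isscalar(eps_r):
        lower = tuple(float(v) for v in lower)
        upper = tuple(float(v) for v in upper)
    return lower, upper


@dataclass(frozen=True)
class TissueDielectricModel:
    """A tissue's nominal spectrum plus its variability bounds.

    ``has_bounds`` is False for tissues modelled without physiological
    variation (skin, and the lymph-node curves); their bound requests
    return the nominal curve.
    """

    name: str
    nominal: ColeColeParams
    bound_fraction: float = DEFAULT_BOUND_FRACTION
    has_bounds: bool = True

    def nominal_at(self, frequency_hz):
        return evaluate_cole_cole(self.nominal, frequency_hz)

    def bounds_at(self, frequency_hz):
        if not self.has_bounds:
            nom = self.nominal_at(frequency_hz)
            return nom, nom
        return build_bounds(self.nominal, frequency_hz, self.bound_fraction)


class MixedTissueModel:
    """Composite bounds for the heterogeneous mixed tissue: lower bound of
    fat, upper bound of muscle, covering the dielectric spread of all the
    tissues compacted into that cluster."""

    name = "mixed"
    has_bounds = True

    def __init__(self, muscle: TissueDielectricModel, fat: TissueDielectricModel):
        if not (muscle.has_bounds and fat.has_bounds):
            raise ConfigError("mixed-tissue bounds need bounded muscle and fat models")
        self.muscle = muscle
        self.fat = fat

    def bounds_at(self, frequency_hz):
        lower, _ = self.fat.bounds_at(frequency_hz)
        _, upper = self.muscle.bounds_at(frequency_hz)
        return lower, upper

    def nominal_at(self, frequency_hz):
        (elo, slo), (ehi, shi) = self.bounds_at(frequency_hz)
        return (elo + ehi) / 2.0, (slo + shi) / 2.0


def mixed_tissue_bounds(muscle: TissueDielectricModel,
                        fat: TissueDielectricModel) -> MixedTissueModel:
    return MixedTissueModel(muscle, fat)


# ---------------------------------------------------------------------------
# registry

_COLE_COLE_COLUMNS = ["tissue", "eps_inf",
                      "deps1", "tau1", "alpha1", "deps2", "tau2", "alpha2",
                      "deps3", "tau3", "alpha3", "deps4", "tau4", "alpha4",
                      "sigma_s", "source"]

#: lymph-node curve name -> label codes that receive it directly
CLN_CURVE_FOR_LABEL = {
    L.CLN_INTERIOR_HEALTHY: "cln_healthy_interior",
    L.CLN_INTERIOR_METASTASIZED: "cln_metastasized_interior",
    L.CLN_SHELL_HEALTHY: "cln_healthy_surface",
    L.CLN_SHELL_METASTASIZED: "cln_metastasized_surface",
}


class DielectricRegistry:
    """Versioned, editable registry of per-tissue dispersion parameters.

    Ships two tables: 4-pole Cole-Cole parameters for skin, bone, fat
    (infiltrated) and muscle, and single-pole Debye parameters for the four
    lymph-node curves (healthy/metastasized × interior/surface).  Users can
    load replacement tables with the same columns.
    """

    def __init__(self, models: dict[str, TissueDielectricModel],
                 bound_fraction: float = DEFAULT_BOUND_FRACTION):
        self.models = models
        self.bound_fraction = bound_fraction
        if "muscle" in models and "fat" in models:
            self.models["mixed"] = mixed_tissue_bounds(models["muscle"], models["fat"])

    @classmethod
    def default(cls, bound_fraction: float = DEFAULT_BOUND_FRACTION) -> "DielectricRegistry":
        pkg = resources.files("hnphantom") / "data"
        return cls.from_tables(pkg / "cole_cole_registry.csv",
                               pkg / "cln_debye_synthetic.csv",
                               bound_fraction=bound_fraction)

    @classmethod
    def from_tables(cls, cole_cole_csv, debye_csv=None,
                    bound_fraction: float = DEFAULT_BOUND_FRACTION) -> "DielectricRegistry":
        cc = pd.read_csv(cole_cole_csv)
        missing = set(_COLE_COLE_COLUMNS) - set(cc.columns)
        if missing:
            raise ConfigError(f"Cole-Cole registry lacks columns {sorted(missing)}")
        models: dict[str, TissueDielectricModel] = {}
        for _, row in cc.iterrows():
            params = ColeColeParams(
                eps_inf=float(row.eps_inf),
                poles=tuple((float(row[f"deps{n}"]), float(row[f"tau{n}"]),
                             float(row[f"alpha{n}"])) for n in (1, 2, 3, 4)),
                sigma_s=float(row.sigma_s),
            )
            name = str(row.tissue)
            # skin has no physiological-variation bounds
            models[name] = TissueDielectricModel(
                name=name, nominal=params, bound_fraction=bound_fraction,
                has_bounds=(name != "skin"))
        if debye_csv is not None:
            dd = pd.read_csv(debye_csv)
            for _, row in dd.iterrows():
                d = DebyeParams(eps_inf=float(row.eps_inf), delta_eps=float(row.delta_eps),
                                tau=float(row.tau), sigma_s=float(row.sigma_s))
                models[str(row.curve)] = TissueDielectricModel(
                    name=str(row.curve), nominal=debye_to_cole_cole(d), has_bounds=False)
        return cls(models, bound_fraction=bound_fraction)

    def model(self, name: str):
        try:
            return self.models[name]
        except KeyError:
            raise ConfigError(f"no dielectric model registered for tissue {name!r}") from None

    def curve_family(self) -> list[tuple[str, str]]:
        """The distinct biological-tissue curves used by the mapping stage:
        one skin curve plus lower/upper bound curves for each of bone, fat
        and muscle — seven in total with the shipped registry."""
        family: list[tuple[str, str]] = []
        for name in ("skin", "bone", "fat", "muscle"):
            m = self.model(name)
            if m.has_bounds:
                family.append((name, "lower"))
                family.append((name, "upper"))
            else:
                family.append((name, "nominal"))
        return family

    def cln_curves(self) -> dict[str, TissueDielectricModel]:
        return {k: self.models[k] for k in sorted(set(CLN_CURVE_FOR_LABEL.values()))
                if k in self.models}


# ---------------------------------------------------------------------------
# intensity -> property mapping


def map_intensity_to_properties(intensity: VoxelVolume, labels: VoxelVolume,
                                registry: DielectricRegistry, frequency_hz: float,
                                ) -> tuple[VoxelVolume, VoxelVolume]:
    """Voxel-wise relative permittivity and conductivity maps at one frequency.

    For each segmented tissue population (fat, muscle, mixed): the minimum
    and maximum MRI intensity over its voxels are anchored to the tissue's
    lower and upper bound curves, and every other voxel is mapped linearly
    in between — independently for permittivity and conductivity.  Skin
    voxels take the single skin-curve value; lymph-node voxels take their
    state-specific interior/surface curve values directly (no intensity
    mapping); background is free space (eps_r = 1, sigma = 0).

    A degenerate population (constant intensity) is assigned the midpoint
    of its bounds rather than raising.
    """
    f = check_frequency(frequency_hz)
    if intensity.data.shape != labels.data.shape:
        raise ConfigError("intensity and label volumes differ in shape")
    lab = labels.data
    inten = np.asarray(intensity.data, dtype=np.float64)
    eps = np.ones(lab.shape, dtype=np.float64)
    sig = np.zeros(lab.shape, dtype=np.float64)

    for tissue, code in L.SEGMENTED_TISSUES.items():
        sel = lab == code
        if not sel.any():
            continue
        (elo, slo), (ehi, shi) = registry.model(tissue).bounds_at(f)
        vals = inten[sel]
        imin, imax = float(vals.min()), float(vals.max())
        if imax == imin:
            logger.warning("tissue %s has constant intensity %.6g; assigning the "
                           "midpoint of its dielectric bounds", tissue, imin)
            frac = np.full(vals.shape, 0.5)
        else:
            frac = (vals - imin) / (imax - imin)
        eps[sel] = elo + frac * (ehi - elo)
        sig[sel] = slo + frac * (shi - slo)

    skin_sel = lab == L.SKIN
    if skin_sel.any():
        e, s = registry.model("skin").nominal_at(f)
        eps[skin_sel] = e
        sig[skin_sel] = s

    for code, curve in CLN_CURVE_FOR_LABEL.items():
        sel = lab == code
        if sel.any():
            e, s = registry.model(curve).nominal_at(f)
            eps[sel] = e
            sig[sel] = s

    return (VoxelVolume(eps, labels.spacing, role="permittivity"),
            VoxelVolume(sig, labels.spacing, role="conductivity"))
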