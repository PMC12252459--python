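"""Leaf heat resistance from chlorophyll-fluorescence (Fv/Fm) heat assays.

Dark-adapted Fv/Fm is measured after independent heating treatments (by
default 25, 35, 45, 55 and 60 degrees C) and on an unheated control (Fmax).
Damage is expressed as photoinactivation

    PhI(T) = (1 - FhT / Fmax) * 100   [%]

and the lethal temperature LT50 is the temperature at which PhI crosses 50 %,
estimated by linear interpolation between the highest treatment with
PhI < 50 % and the lowest treatment with PhI > 50 %.  Curves that never reach
50 % are right-censored at the hottest treatment; curves already above 50 % at
the mildest treatment are left-censored.  Fitting a parametric sigmoid is
deliberately not the primary estimator; the bracketing interpolation is the
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayCurve",
    "AssayProtocol",
    "LT50Estimate",
    "photoinactivation",
    "estimate_lt50",
    "species_summary",
    "curves_from_frame",
    "estimates_to_frame",
]

#: Treatment temperatures (degrees C) of the standard assay.
DEFAULT_TREATMENTS = (25.0, 35.0, 45.0, 55.0, 60.0)


@dataclass(frozen=True)
class AssayProtocol:
    """Thermal protocol metadata of the heat assay (no computation).

    Leaves start at 15 degrees C, are ramped at 10 K/h to the target
    treatment temperature, held there for 2 h, and returned at the same rate.
    """

    start_temp_c: float = 15.0
    ramp_k_per_h: float = 10.0
    hold_h: float = 2.0
    treatments_c: tuple[float, ...] = DEFAULT_TREATMENTS

    def __post_init__(self) -> None:
        if self.ramp_k_per_h <= 0:
            raise ValueError("heating rate must be > 0")
        if any(b <= a for a, b in zip(self.treatments_c, self.treatments_c[1:])):
            raise ValueError("treatment temperatures must be strictly increasing")


@dataclass
class AssayCurve:
    """Per-individual Fv/Fm response to the heating treatments."""

    individual: str
    species: str
    temperatures: np.ndarray  # treatment temperatures, degrees C, ascending
    fvfm: np.ndarray  # Fv/Fm at each treatment, in [0, 1] up to noise
    fmax: float  # control (unheated) Fv/Fm
    growth_form: str = ""
    true_lt50: float | None = None  # retained by the synthetic generator

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fvfm = np.asarray(self.fvfm, dtype=float)
        if self.temperatures.size < 2:
            raise ValueError("need at least 2 treatment temperatures")
        if self.temperatures.size != self.fvfm.size:
            raise ValueError("temperatures and fvfm length mismatch")
        if np.unique(self.temperatures).size != self.temperatures.size:
            raise ValueError("treatment temperatures must be unique")
        if not np.all(np.diff(self.temperatures) > 0):
            order = np.argsort(self.temperatures)
            self.temperatures = self.temperatures[order]
            self.fvfm = self.fvfm[order]
        if self.fmax <= 0:
            raise ValueError("control Fv/Fm (Fmax) must be > 0")

    def phi(self) -> np.ndarray:
        """Photoinactivation (%) at each treatment temperature, unclipped."""
        return photoinactivation(self.fvfm, self.fmax, clip=False)


@dataclass
class LT50Estimate:
    """LT50 outcome for one individual.

    ``status`` is ``interpolated`` (value defined, bracket recorded),
    ``right_censored`` (damage never exceeded 50 %; ``bound`` is the hottest
    treatment) or ``left_censored`` (damage already above 50 % at the mildest
    treatment; ``bound`` is that temperature).
    """

    individual: str
    species: str
    status: str
    value: float | None = None  # degrees C, only when interpolated
    bound: float | None = None  # censoring bound, degrees C
    bracket: tuple[float, float] | None = None  # (T_lo, T_hi) when interpolated
    non_monotone: bool = False
    growth_form: str = ""


def photoinactivation(fht, fmax: float, clip: bool = False):
    """PhI = (1 - FhT/Fmax) * 100, in percent.

    With ``clip=True`` values are clipped to [0, 100] for reporting; the raw
    value (possibly negative when a heated leaf out-fluoresces the control)
    is what the LT50 bracketing uses.
    """
    if fmax <= 0:
        raise ValueError("Fmax must be > 0")
    fht_arr = np.asarray(fht, dtype=float)
    if np.any(fht_arr < 0):
        raise ValueError("Fv/Fm must be >= 0")
    out = (1.0 - fht_arr / fmax) * 100.0
    if clip:
        out = np.clip(out, 0.0, 100.0)
    return float(out) if np.ndim(fht) == 0 else out


def estimate_lt50(curve: AssayCurve) -> LT50Estimate:
    """Bracketing linear interpolation of the 50 % photoinactivation crossing.

    Let ``T_lo`` be the highest treatment with PhI < 50 and ``T_hi`` the
    lowest with PhI > 50.  When ``T_lo < T_hi`` the estimate is the linear
    interpolant between the two; PhI exactly 50 at a node returns that node.
    Curves whose PhI sequence is non-monotone around 50 % (possible with
    measurement noise) use the first upward 50 % crossing in temperature
    order and carry a ``non_monotone`` flag.
    """
    temps = curve.temperatures
    phi = curve.phi()  # raw, negative PhI counts as < 50 for bracketing

    exact = np.flatnonzero(phi == 50.0)
    if exact.size:
        t = float(temps[exact[0]])
        return LT50Estimate(
            curve.individual, curve.species, "interpolated",
            value=t, bracket=(t, t), growth_form=curve.growth_form,
        )

    below = np.flatnonzero(phi < 50.0)
    above = np.flatnonzero(phi > 50.0)
    if above.size == 0:
        return LT50Estimate(
            curve.individual, curve.species, "right_censored",
            bound=float(temps[-1]), growth_form=curve.growth_form,
        )
    if below.size == 0:
        return LT50Estimate(
            curve.individual, curve.species, "left_censored",
            bound=float(temps[0]), growth_form=curve.growth_form,
        )

    i_lo = below[-1]  # highest T with PhI < 50
    i_hi = above[0]  # lowest T with PhI > 50
    non_monotone = i_lo > i_hi
    if non_monotone:
        # first adjacent upward crossing of 50 % in temperature order
        up = np.flatnonzero((phi[:-1] < 50.0) & (phi[1:] > 50.0))
        if up.size == 0:
            # starts above 50 and only dips below later: no upward crossing
            warnings.warn(
                f"{curve.individual}: PhI starts above 50% and never re-crosses; "
                "treating as left-censored", stacklevel=2,
            )
            return LT50Estimate(
                curve.individual, curve.species, "left_censored",
                bound=float(temps[0]), non_monotone=True,
                growth_form=curve.growth_form,
            )
        i_lo, i_hi = up[0], up[0] + 1
        warnings.warn(
            f"{curve.individual}: non-monotone PhI sequence; "
            "using first upward 50% crossing", stacklevel=2,
        )

    t_lo, t_hi = float(temps[i_lo]), float(temps[i_hi])
    p_lo, p_hi = float(phi[i_lo]), float(phi[i_hi])
    value = t_lo + (50.0 - p_lo) * (t_hi - t_lo) / (p_hi - p_lo)
    return LT50Estimate(
        curve.individual, curve.species, "interpolated",
        value=value, bracket=(t_lo, t_hi), non_monotone=non_monotone,
        growth_form=curve.growth_form,
    )


def species_summary(
    estimates: list[LT50Estimate], by: str = "species"
) -> pd.DataFrame:
    """Group means and dispersions of interpolated LT50 values.

    Censored individuals are excluded from means and reported in the
    ``n_censored`` column.  Groups with a single interpolated value have
    ``sd`` = NaN; all-censored groups report counts only.
    """
    if by not in ("species", "growth_form"):
        raise ValueError("grouping must be 'species' or 'growth_form'")
    frame = estimates_to_frame(estimates)
    rows = []
    for key, grp in frame.groupby(by, sort=True):
        ok = grp[grp["status"] == "interpolated"]["lt50"]
        rows.append(
            {
                by: key,
                "mean_lt50": float(ok.mean()) if len(ok) else float("nan"),
                "sd_lt50": float(ok.std(ddof=1)) if len(ok) >= 2 else float("nan"),
                "n": int(len(ok)),
                "n_censored": int((grp["status"] != "interpolated").sum()),
            }
        )
    return pd.DataFrame(rows)


def curves_from_frame(frame: pd.DataFrame) -> list[AssayCurve]:
    """Build assay curves from a long table.

    Expected columns: ``individual, species, treatment_temp_C, fvfm,
    is_control`` (optional ``growth_form``).  Control rows (``is_control``
    truthy) supply Fmax; when an individual has several control leaves their
    mean Fv/Fm is the control value.  Several leaves at one treatment
    temperature are averaged per individual before bracketing.
    """
    required = {"individual", "species", "treatment_temp_C", "fvfm", "is_control"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    curves = []
    for ind, grp in frame.groupby("individual", sort=True):
        ctrl = grp[grp["is_control"].astype(bool)]
        if ctrl.empty:
            raise ValueError(f"individual {ind!r} has no control measurement")
        heated = grp[~grp["is_control"].astype(bool)]
        mean_by_t = heated.groupby("treatment_temp_C")["fvfm"].mean()
        curves.append(
            AssayCurve(
                individual=str(ind),
                species=str(grp["species"].iloc[0]),
                temperatures=mean_by_t.index.to_numpy(dtype=float),
                fvfm=mean_by_t.to_numpy(dtype=float),
                fmax=float(ctrl["fvfm"].mean()),
                growth_form=str(grp["growth_form"].iloc[0])
                if "growth_form" in grp
                else "",
            )
        )
    return curves


def estimates_to_frame(estimates: list[LT50Estimate]) -> pd.DataFrame:
    """LT50 output table with a status column (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "individual": e.individual,
                "species": e.species,
                "growth_form": e.growth_form,
                "lt50": e.value if e.value is not None else float("nan"),
                "status": e.status,
                "bound": e.bound if e.bound is not None else float("nan"),
                "non_monotone": e.non_monotone,
            }
            for e in estimates
        ]
    )
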