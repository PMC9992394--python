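"""Interconversion of soil phosphorus tests to Olsen P.

Different extraction tests (Bray-I, Mehlich-3, Resin, Kirsanov, AB-DPTA)
measure overlapping but distinct pools of soil phosphorus.  Published linear
regressions map each test onto Olsen P; where several studies report
regressions for the same (test, soil-class) pair, a single combined equation
is formed by weighting slope, intercept and R^2 by each study's sample size.
Calcareous and non-calcareous soils carry separate Mehlich-3 and Resin
equations because acid extractants dissolve calcium phosphates that are
sparingly available to plants; Bray-I values from soils at pH >= 7 are
rejected outright for the same reason.  Kirsanov (0.2 N HCl) has no published
Olsen regression and is routed through the combined Bray-I equation as the
closest-matching extractant.

The component equations shipped with the package live in
``data/table2_components.csv``; :func:`build_default_registry` combines them
into the applied equations (Mehlich-3 non-calcareous 0.47x + 2.4, calcareous
0.41x + 1.1, Bray-I 0.49x + 3.1, AB-DPTA 1.81x + 4.1, Resin 0.71x + 0.1 /
0.94x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Method, SoilClass

__all__ = [
    "ConversionEquation", "ConversionRegistry", "ConversionError",
    "weighted_mean_equation", "build_default_registry", "load_components",
    "validate_conversion", "classify_calcareous",
]

#: pH at or above which Bray-I (and, by extension, Kirsanov) data are rejected.
BRAY1_PH_CUTOFF = 7.0

#: pH at or above which an unclassified soil is treated as calcareous.
CALCAREOUS_PH_DEFAULT = 7.5


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionEquation:
    """olsen = slope * source_test + intercept (mg P kg^-1)."""

    method: Method
    soil_class: SoilClass
    slope: float
    intercept: float
    r_squared: Optional[float] = None
    n_samples: int = 1
    jurisdiction: str = ""
    source_ref: str = ""

    def __post_init__(self):
        if self.slope <= 0:
            raise ConversionError(f"slope must be positive, got {self.slope}")
        if self.n_samples < 1:
            raise ConversionError("n_samples must be >= 1")
        if self.r_squared is not None and not (0 <= self.r_squared <= 1):
            raise ConversionError(f"r_squared out of [0,1]: {self.r_squared}")

    @property
    def equation_id(self) -> str:
        return f"{self.method.value}:{self.soil_class.value}"

    def apply(self, value: float) -> float:
        """Convert a source-test concentration; floored at zero."""
        if value < 0:
            raise ConversionError(f"invalid concentration {value}")
        return max(0.0, self.slope * value + self.intercept)

    def invert(self, olsen: float) -> float:
        """Source-test value whose conversion equals ``olsen`` (generator use)."""
        return (olsen - self.intercept) / self.slope

    def as_printed(self) -> "ConversionEquation":
        """Coefficients at published display precision.

        The published combined slopes are truncated (not rounded) to two
        decimals — 0.4772 prints as 0.47 and 0.4975 as 0.49 — while
        intercepts round to one decimal and R^2 to two.  This mirrors that
        display convention so a registry rebuilt from the component rows
        matches the published equations digit for digit.
        """
        return replace(
            self,
            slope=math.floor(self.slope * 100 + 1e-9) / 100,
            intercept=round(self.intercept, 1),
            r_squared=None if self.r_squared is None else round(self.r_squared, 2),
        )


def weighted_mean_equation(
    equations: Sequence[ConversionEquation],
) -> ConversionEquation:
    """Combine same-test equations, weighting every coefficient by sample size.

    slope = sum(n_i * slope_i) / sum(n_i), and identically for the intercept
    and R^2 (equations lacking R^2 are excluded from the R^2 average only).
    Full precision is retained; use :meth:`ConversionEquation.as_printed` for
    the display form.
    """
    if not equations:
        raise ConversionError("no equations to combine")
    methods = {e.method for e in equations}
    classes = {e.soil_class for e in equations}
    if len(methods) > 1:
        raise ConversionError(f"incompatible equations: methods {methods}")
    if len(equations) == 1:
        return equations[0]
    n = np.array([e.n_samples for e in equations], dtype=float)
    slope = float(np.average([e.slope for e in equations], weights=n))
    intercept = float(np.average([e.intercept for e in equations], weights=n))
    with_r2 = [e for e in equations if e.r_squared is not None]
    r2 = None
    if with_r2:
        nr = np.array([e.n_samples for e in with_r2], dtype=float)
        r2 = float(np.average([e.r_squared for e in with_r2], weights=nr))
    return ConversionEquation(
        method=equations[0].method,
        soil_class=classes.pop() if len(classes) == 1 else SoilClass.ANY,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_samples=int(n.sum()),
        jurisdiction="combined",
        source_ref="weighted mean of " + ",".join(e.source_ref for e in equations),
    )


def classify_calcareous(
    soil_class: SoilClass,
    pH: Optional[float],
    ph_cutoff: float = CALCAREOUS_PH_DEFAULT,
) -> SoilClass:
    """Resolve an unknown soil class: calcareous iff pH >= cutoff (default 7.5)."""
    if soil_class in (SoilClass.CALCAREOUS, SoilClass.NON_CALCAREOUS):
        return soil_class
    if pH is not None and not (isinstance(pH, float) and math.isnan(pH)) \
            and pH >= ph_cutoff:
        return SoilClass.CALCAREOUS
    return SoilClass.NON_CALCAREOUS


@dataclass
class Rejection:
    """A record the registry refuses to convert, with the routing reason."""

    reason: str

    def __bool__(self):  # a rejection is falsy so `if eq:` reads naturally
        return False


class ConversionRegistry:
    """Combined conversion equations keyed by (method, soil class).

    Routing rules: Olsen needs no conversion; Bray-I and Kirsanov are rejected
    at pH >= 7; Kirsanov aliases to the combined Bray-I equation; AB-DPTA has
    a single class-free equation; Mehlich-3 and Resin resolve per soil class,
    with unknown classes classified from pH.
    """

    def __init__(
        self,
        components: Iterable[ConversionEquation],
        printed: bool = True,
        bray1_ph_cutoff: float = BRAY1_PH_CUTOFF,
        kirsanov_as_bray1: bool = True,
    ):
        self.components = list(components)
        self.bray1_ph_cutoff = bray1_ph_cutoff
        self.kirsanov_as_bray1 = kirsanov_as_bray1
        self.combined: dict[tuple[Method, SoilClass], ConversionEquation] = {}
        groups: dict[tuple[Method, SoilClass], list[ConversionEquation]] = {}
        for eq in self.components:
            groups.setdefault((eq.method, eq.soil_class), []).append(eq)
        for key, eqs in groups.items():
            combined = weighted_mean_equation(eqs)
            self.combined[key] = combined.as_printed() if printed else combined

    def resolve(
        self,
        method: Method,
        soil_class: SoilClass = SoilClass.UNKNOWN,
        pH: Optional[float] = None,
    ):
        """Equation for a record, ``None`` for Olsen identity, or a Rejection."""
        method = Method(method)
        if method is Method.OLSEN:
            return None
        if method in (Method.BRAY1, Method.KIRSANOV):
            if pH is not None and not (isinstance(pH, float) and math.isnan(pH)) \
                    and pH >= self.bray1_ph_cutoff:
                return Rejection("pH")
            key_method = Method.BRAY1 if (
                method is Method.KIRSANOV and self.kirsanov_as_bray1) else method
            key = (key_method, SoilClass.NON_CALCAREOUS)
            if key not in self.combined:
                raise ConversionError(f"no conversion available for {method}")
            return self.combined[key]
        if method is Method.ABDPTA:
            key = (Method.ABDPTA, SoilClass.ANY)
            if key not in self.combined:
                raise ConversionError("no conversion available for abdpta")
            return self.combined[key]
        # mehlich3 / resin: class-specific
        cls = classify_calcareous(soil_class, pH)
        key = (method, cls)
        if key not in self.combined:
            raise ConversionError(f"no conversion available for {method}/{cls}")
        return self.combined[key]

    def to_olsen(
        self,
        value: float,
        method: Method,
        soil_class: SoilClass = SoilClass.UNKNOWN,
        pH: Optional[float] = None,
    ):
        """(olsen value, provenance tag) or (None, rejection reason)."""
        eq = self.resolve(method, soil_class, pH)
        if eq is None:
            if value < 0:
                raise ConversionError(f"invalid concentration {value}")
            return value, "olsen:identity"
        if isinstance(eq, Rejection):
            return None, f"rejected:{eq.reason}"
        return eq.apply(value), eq.equation_id

    def convert_table(self, df: pd.DataFrame) -> pd.DataFrame:
        """Vectorised conversion of a sample table.

        Adds ``olsen_p`` (NaN where rejected), ``converted_from`` and
        ``equation_id`` columns; the input is not modified.
        """
        out = df.copy()
        olsen = np.full(len(df), np.nan)
        eq_id = np.empty(len(df), dtype=object)
        for i, row in enumerate(df.itertuples(index=False)):
            ph = getattr(row, "pH", None)
            ph = None if ph is None or (isinstance(ph, float) and math.isnan(ph)) else float(ph)
            sc = getattr(row, "soil_class", SoilClass.UNKNOWN.value)
            try:
                sc = SoilClass(sc)
            except ValueError:
                sc = SoilClass.UNKNOWN
            val, tag = self.to_olsen(float(row.value), Method(row.method), sc, ph)
            olsen[i] = np.nan if val is None else val
            eq_id[i] = tag
        out["olsen_p"] = olsen
        out["converted_from"] = df["method"].values
        out["equation_id"] = eq_id
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": eq.method.value, "soil_class": eq.soil_class.value,
             "slope": eq.slope, "intercept": eq.intercept,
             "r_squared": eq.r_squared, "n_samples": eq.n_samples,
             "jurisdiction": eq.jurisdiction, "source_ref": eq.source_ref}
            for eq in self.combined.values()
        ]
        return pd.DataFrame(rows)


def load_components(path=None) -> list[ConversionEquation]:
    """Load component equations from CSV (default: the packaged registry)."""
    if path is None:
        src = resources.files("olsenp.data") / "table2_components.csv"
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    eqs = []
    for r in df.itertuples(index=False):
        r2 = getattr(r, "r_squared", None)
        if r2 is not None and (pd.isna(r2)):
            r2 = None
        eqs.append(ConversionEquation(
            method=Method(r.method), soil_class=SoilClass(r.soil_class),
            slope=float(r.slope), intercept=float(r.intercept),
            r_squared=None if r2 is None else float(r2),
            n_samples=int(r.n_samples),
            jurisdiction=str(getattr(r, "jurisdiction", "")),
            source_ref=str(getattr(r, "source_ref", "")),
        ))
    return eqs


def build_default_registry(printed: bool = True, **kwargs) -> ConversionRegistry:
    """Registry combining the packaged component equations.

    ``printed=True`` (default) stores the combined equations at published
    display precision — the coefficients the equations are actually applied
    with; ``printed=False`` keeps full weighted-mean precision.
    """
    return ConversionRegistry(load_components(), printed=printed, **kwargs)


def validate_conversion(source_values, measured_olsen, equation: ConversionEquation):
    """Regress measured Olsen P on equation-predicted Olsen P.

    Returns {'slope', 'intercept', 'p_value', 'nse', 'n'}: a conversion
    equation fit for general use shows slope near 1 and positive
    Nash-Sutcliffe efficiency of the predictions.
    """
    import statsmodels.api as sm

    source_values = np.asarray(source_values, dtype=float)
    measured = np.asarray(measured_olsen, dtype=float)
    if source_values.size < 3 or source_values.size != measured.size:
        raise ConversionError("need >= 3 paired observations")
    predicted = np.array([equation.apply(v) for v in source_values])
    if np.ptp(predicted) == 0:
        raise ConversionError("no variance in predictions")
    X = sm.add_constant(predicted)
    fit = sm.OLS(measured, X).fit()
    nse = 1.0 - np.sum((measured - predicted) ** 2) / np.sum(
        (measured - measured.mean()) ** 2)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p_value": float(fit.pvalues[1]),
        "nse": float(nse),
        "n": int(measured.size),
    }
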