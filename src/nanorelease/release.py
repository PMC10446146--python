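"""Release quantification from filter-based Ti gravimetry.

Particles emitted by the photocatalytic surfaces are collected on a quartz
filter and the titanium mass is assayed by ICP-MS. When the Ti mass falls
below the assay's limit of quantification (LOQ), the sample is censored and
every derived quantity becomes an upper bound, computed by substituting the
LOQ for the unknown mass.

The derived chain for each sample:

    Ti concentration   = mass (or LOQ) / sampled air volume        [ng/m3]
    TiO2 concentration = Ti concentration * (M_TiO2 / M_Ti)        [ng/m3]
    emission rate      = TiO2 concentration * mean flow            [ng/h]
    release factor     = TiO2 concentration / photoactive area     [ng/(m2*m3)]

where mean flow = sampled volume / duration. The release factor normalises
the emission by both photoactive surface area and ventilated air volume, so
it transfers to other devices: multiplying it by a device's coated area and
volume flow predicts that device's emission rate.

Two output modes exist: ``raw`` (full-precision chain) and ``table1``, a
printed-report mode that reproduces fixed-significant-figure report cells
(Ti and TiO2 concentrations at 1 significant figure, the emission rate at 2
computed from the unrounded concentration, and the release factor at 3
computed from the printed TiO2 concentration).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .units import round_sig, ti_to_tio2

__all__ = [
    "FilterSample",
    "SurfaceSpec",
    "ReleaseFactors",
    "bound_ti_concentration",
    "release_factors",
    "table1_report",
    "format_report_text",
]


@dataclass(frozen=True)
class FilterSample:
    """One gravimetric filter result, possibly censored at the LOQ.

    ti_mass_ng is None for a censored sample (Ti below the LOQ).
    """

    label: str
    ti_mass_ng: float | None
    loq_ng: float
    sampled_volume_m3: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.loq_ng <= 0:
            raise ValueError("loq_ng must be > 0")
        if self.sampled_volume_m3 <= 0:
            raise ValueError("sampled_volume_m3 must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.ti_mass_ng is not None and self.ti_mass_ng < 0:
            raise ValueError("ti_mass_ng must be >= 0 when measured")

    @property
    def censored(self) -> bool:
        return self.ti_mass_ng is None

    @property
    def mean_flow_m3_h(self) -> float:
        """Empirical mean sampling flow, volume / duration (m3/h)."""
        return self.sampled_volume_m3 / self.duration_h


@dataclass(frozen=True)
class SurfaceSpec:
    """Photoactive surface geometry: n identical coated units."""

    n_units: int = 3
    area_per_unit_m2: float = 0.009  # 90 cm2 honeycomb inner surface

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.area_per_unit_m2 <= 0:
            raise ValueError("area_per_unit_m2 must be > 0")

    @property
    def total_area_m2(self) -> float:
        return self.n_units * self.area_per_unit_m2


@dataclass(frozen=True)
class ReleaseFactors:
    """Raw and printed release quantities for one filter sample.

    is_upper_bound is True whenever the underlying sample was censored, in
    which case every value is an upper bound on the true release.
    The printed_* fields follow the fixed-significant-figure report chain.
    """

    label: str
    is_upper_bound: bool
    mean_flow_m3_h: float
    conc_ti_ng_m3: float
    conc_tio2_ng_m3: float
    rate_tio2_ng_h: float
    rf_tio2_ng_m2_m3: float
    printed_conc_ti_ng_m3: float
    printed_conc_tio2_ng_m3: float
    printed_rate_tio2_ng_h: float
    printed_rf_tio2_ng_m2_m3: float


def bound_ti_concentration(sample: FilterSample) -> tuple[float, bool]:
    """Ti air concentration (ng/m3) and whether it is a censored upper bound.

    Censored samples use the LOQ as the largest mass consistent with the
    assay, giving LOQ / volume as an upper bound on the concentration.
    """
    if sample.censored:
        return sample.loq_ng / sample.sampled_volume_m3, True
    return sample.ti_mass_ng / sample.sampled_volume_m3, False


def release_factors(sample: FilterSample, surface: SurfaceSpec) -> ReleaseFactors:
    """Full raw + printed release chain for one sample."""
    conc_ti, upper = bound_ti_concentration(sample)
    conc_tio2 = ti_to_tio2(conc_ti)
    flow = sample.mean_flow_m3_h
    rate = conc_tio2 * flow
    rf = conc_tio2 / surface.total_area_m2

    # printed chain: concentrations at 1 significant figure (TiO2 converted
    # from the printed Ti value), rate at 2 from the raw concentration, and
    # the release factor at 3 from the printed TiO2 concentration
    p_ti = round_sig(conc_ti, 1)
    p_tio2 = round_sig(ti_to_tio2(p_ti), 1)
    p_rate = round_sig(rate, 2)
    p_rf = round_sig(p_tio2 / surface.total_area_m2, 3)

    return ReleaseFactors(
        label=sample.label,
        is_upper_bound=upper,
        mean_flow_m3_h=flow,
        conc_ti_ng_m3=conc_ti,
        conc_tio2_ng_m3=conc_tio2,
        rate_tio2_ng_h=rate,
        rf_tio2_ng_m2_m3=rf,
        printed_conc_ti_ng_m3=p_ti,
        printed_conc_tio2_ng_m3=p_tio2,
        printed_rate_tio2_ng_h=p_rate,
        printed_rf_tio2_ng_m2_m3=p_rf,
    )


_ROUNDED_COLS = {
    "ti_ng_m3": "printed_conc_ti_ng_m3",
    "tio2_ng_m3": "printed_conc_tio2_ng_m3",
    "tio2_ng_h": "printed_rate_tio2_ng_h",
    "tio2_ng_m2_m3": "printed_rf_tio2_ng_m2_m3",
}
_RAW_COLS = {
    "ti_ng_m3": "conc_ti_ng_m3",
    "tio2_ng_m3": "conc_tio2_ng_m3",
    "tio2_ng_h": "rate_tio2_ng_h",
    "tio2_ng_m2_m3": "rf_tio2_ng_m2_m3",
}


def table1_report(
    samples: list[FilterSample],
    surface: SurfaceSpec,
    rounding: str = "table1",
) -> pd.DataFrame:
    """One report row per sample: sampling parameters and release bounds.

    rounding="table1" emits the printed-report chain, "raw" the unrounded
    values; censoring is a boolean column (human-readable "<" prefixes are
    applied by format_report_text, never stored in the data).
    """
    if not samples:
        raise ValueError("at least one filter sample is required")
    if rounding not in ("table1", "raw"):
        raise ValueError("rounding must be 'table1' or 'raw'")
    cols = _ROUNDED_COLS if rounding == "table1" else _RAW_COLS
    rows = []
    for sample in samples:
        rf = release_factors(sample, surface)
        row = {
            "label": sample.label,
            "duration_h": sample.duration_h,
            "volume_m3": sample.sampled_volume_m3,
        }
        row.update({out: getattr(rf, attr) for out, attr in cols.items()})
        row["censored"] = rf.is_upper_bound
        rows.append(row)
    return pd.DataFrame(rows)


def format_report_text(report: pd.DataFrame) -> str:
    """Human-readable rendering with '<' prefixes on censored bounds."""
    display = report.copy()
    value_cols = [c for c in _ROUNDED_COLS if c in display.columns]
    for col in value_cols:
        display[col] = [
            ("<" if cens else "") + f"{val:g}"
            for val, cens in zip(display[col], display["censored"])
        ]
    return display.drop(columns=["censored"]).to_string(index=False)
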