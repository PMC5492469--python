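"""Derived water-chemistry quantities, chiefly the eutrophication index (EI).

EI = DIN * DIP * COD * 1e6 / 4500, with DIN the dissolved inorganic nitrogen
(NO3-N + NO2-N + NH4-N, mg/L), DIP the soluble phosphate (PO4-P, mg/L) and COD
the chemical oxygen demand (mg/L).  Values of 1 or more indicate a eutrophic
water body.

Concentrations reported below the detection limit must be substituted before
the product can be formed.  The default policy replaces ``<x`` by the limit
``x`` itself; replacing by zero or half the limit is exposed for sensitivity
analyses.  Every substitution that was applied is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import BelowDetection, WaterChemistryRecord

__all__ = ["EutrophicationResult", "compute_ei", "ei_table", "load_bloom_chemistry"]

#: Divisor of the EI formula (mg^3 L^-3 scale constant).
EI_DENOMINATOR = 4500.0

_POLICIES = ("limit", "zero", "half_limit")


@dataclass
class EutrophicationResult:
    sample_id: str
    din: float
    dip: float
    cod: float
    ei: float
    substitutions_applied: list[tuple[str, float]] = field(default_factory=list)


def _resolve(record: WaterChemistryRecord, name: str, policy: str,
             substitutions: list[tuple[str, float]]) -> float:
    value = getattr(record, name)
    if value is None:
        raise ValueError(f"missing required variable {name!r} for sample {record.sample_id!r}")
    if isinstance(value, BelowDetection):
        substitutions.append((name, value.limit))
        if policy == "limit":
            return value.limit
        if policy == "half_limit":
            return value.limit / 2.0
        return 0.0
    return float(value)


def compute_ei(record: WaterChemistryRecord, *, below_detection: str = "limit") -> EutrophicationResult:
    """Compute the eutrophication index for one sample.

    Parameters
    ----------
    record : WaterChemistryRecord
        Must carry NO3_N, NO2_N, NH4_N, PO4_P and COD (numeric or
        below-detection).
    below_detection : {"limit", "zero", "half_limit"}
        Substitution policy for below-detection concentrations.  ``"limit"``
        (the default) reproduces published EI values computed from rounded
        field-table inputs.
    """
    if below_detection not in _POLICIES:
        raise ValueError(f"below_detection must be one of {_POLICIES}, got {below_detection!r}")
    subs: list[tuple[str, float]] = []
    din = sum(_resolve(record, n, below_detection, subs) for n in ("NO3_N", "NO2_N", "NH4_N"))
    dip = _resolve(record, "PO4_P", below_detection, subs)
    cod = _resolve(record, "COD", below_detection, subs)
    ei = din * dip * cod * 1e6 / EI_DENOMINATOR
    return EutrophicationResult(record.sample_id, din, dip, cod, ei, subs)


def ei_table(records: list[WaterChemistryRecord], *, below_detection: str = "limit") -> list[EutrophicationResult]:
    """Compute EI for a list of samples (one result per record, order kept)."""
    return [compute_ei(r, below_detection=below_detection) for r in records]


def load_bloom_chemistry() -> list[WaterChemistryRecord]:
    """Bundled water-chemistry measurements from a *Microcystis* bloom survey.

    Twelve surface-water samples from four stations of a eutrophic plateau
    lake during a late-bloom campaign; phosphate is below the 0.01 mg/L
    detection limit in most samples.  Useful as a worked example for
    :func:`compute_ei` and the metadata parser.
    """
    from importlib.resources import files

    from .io import read_metadata_table

    return read_metadata_table(str(files("bloomnet") / "data" / "bloom_water_chemistry.tsv"))
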