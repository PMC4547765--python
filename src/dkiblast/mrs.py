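"""Metabolite table quality control and total-creatine ratios.

Consumes spectral-fit output at the fitted-concentration level (one row per
metabolite with its Cramér-Rao lower bound, CRLB %), applies the
reliability gate — only metabolites with CRLB strictly below the threshold
(default 20%) are analyzed further — and expresses retained concentrations
relative to total creatine (tCr), the usual internal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "KNOWN_METABOLITES",
    "MetaboliteRecord",
    "load_metabolite_table",
    "filter_crlb",
    "ratio_to_tcr",
    "ratios_to_longitudinal_rows",
]

KNOWN_METABOLITES = frozenset(
    {
        "NAA", "NAAG", "Cho", "tCho", "Ins", "Tau", "Gln", "Glu", "Glx",
        "Lac", "tCr", "GABA", "GSH", "Asp", "Ala", "Glc", "MM",
    }
)

REQUIRED_COLUMNS = ("name", "concentration", "crlb_percent")


@dataclass(frozen=True)
class MetaboliteRecord:
    name: str
    concentration: float  # institutional units
    crlb_percent: float

    def __post_init__(self):
        if not self.name:
            raise ValueError("metabolite name must be non-empty")
        if self.crlb_percent < 0:
            raise ValueError("CRLB must be >= 0")


def load_metabolite_table(path, dialect: str = "csv"):
    """Read metabolite records from a simple CSV: name,concentration,crlb_percent.

    Unknown metabolite names are passed through (with a warning list
    returned alongside), so site-specific basis sets do not break ingestion.
    Returns ``(records, warnings)``.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metabolite table lacks columns {missing}")
    records = [
        MetaboliteRecord(str(r["name"]), float(r["concentration"]), float(r["crlb_percent"]))
        for _, r in df.iterrows()
    ]
    warnings = [
        f"unknown metabolite name: {r.name}"
        for r in records
        if r.name not in KNOWN_METABOLITES
    ]
    return records, warnings


def filter_crlb(records, threshold_percent: float = 20.0):
    """Retain records with CRLB strictly below the threshold.

    The gate is strict ("less than"), so a CRLB exactly at the threshold is
    excluded. Order-preserving and idempotent. Returns
    ``(retained, excluded)``.
    """
    if threshold_percent <= 0:
        raise ValueError("threshold must be > 0")
    retained = [r for r in records if r.crlb_percent < threshold_percent]
    excluded = [r for r in records if r.crlb_percent >= threshold_percent]
    return retained, excluded


def ratio_to_tcr(records) -> pd.DataFrame:
    """Concentration ratios relative to total creatine.

    Requires a tCr record with positive concentration among the (already
    gated) records; the trivial tCr/tCr = 1 row is omitted. Ratios are
    invariant to a global concentration rescaling.
    """
    tcr = [r for r in records if r.name == "tCr"]
    if not tcr:
        raise ValueError("tCr record missing: voxel unusable for ratios")
    tcr_conc = tcr[0].concentration
    if tcr_conc <= 0:
        raise ValueError("tCr concentration <= 0: voxel unusable for ratios")
    rows = [
        dict(metabolite=r.name, ratio=r.concentration / tcr_conc)
        for r in records
        if r.name != "tCr"
    ]
    return pd.DataFrame(rows, columns=["metabolite", "ratio"])


def ratios_to_longitudinal_rows(
    ratios: pd.DataFrame, subject: str, group: str, time: str, region: str
) -> pd.DataFrame:
    """Reshape ratio rows into longitudinal-table records (measure "X/tCr")."""
    return pd.DataFrame(
        [
            dict(
                subject=subject,
                group=group,
                time=time,
                region=region,
                measure=f"{r.metabolite}/tCr",
                value=r.ratio,
            )
            for r in ratios.itertuples()
        ]
    )
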