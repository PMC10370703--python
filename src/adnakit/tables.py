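"""TSV table readers and the JSON run report.

Isotope tables carry the header: individual, element, d13C, d15N, C_pct,
N_pct.  Craniometric tables carry: individual, kind, value.  The run
report is a flat {module -> results} JSON object.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .isotopes import IsotopeSample

ISOTOPE_COLUMNS = ["individual", "element", "d13C", "d15N", "C_pct", "N_pct"]


def read_isotope_table(path: str | Path) -> list[IsotopeSample]:
    """Read a per-sample isotope TSV into IsotopeSample records."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        IsotopeSample(
            individual=str(row.individual),
            skeletal_element=str(row.element),
            d13c=float(row.d13C),
            d15n=float(row.d15N),
            c_pct=float(row.C_pct),
            n_pct=float(row.N_pct),
        )
        for row in df.itertuples()
    ]


def write_isotope_table(samples: list[IsotopeSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "individual": s.individual,
                "element": s.skeletal_element,
                "d13C": s.d13c,
                "d15N": s.d15n,
                "C_pct": s.c_pct,
                "N_pct": s.n_pct,
            }
            for s in samples
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_craniometric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual", "kind", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_report(results: dict, path: str | Path) -> None:
    """Write the {module -> results} JSON run report."""
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
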