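"""Writers that turn scenario results into reproducible output files.

Each scenario emits a long-format CSV (RFC-4180, '.' decimal, full
``repr`` precision so a round-trip read restores every float exactly)
and a JSON sidecar carrying the seed, grids, rates and software version
— enough to regenerate the CSV byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .scenarios import ScenarioResult

__all__ = ["write_result", "read_result_table"]


def write_result(result: ScenarioResult, outdir: str | Path, overwrite: bool = False) -> Path:
    """Write ``<scenario>.csv`` + ``<scenario>.json`` under ``outdir``.

    Returns the CSV path.  Refuses to clobber an existing file unless
    ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{result.scenario}.csv"
    json_path = outdir / f"{result.scenario}.json"
    if not overwrite:
        for p in (csv_path, json_path):
            if p.exists():
                raise FileExistsError(f"{p} exists (pass overwrite=True to replace)")
    result.table.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(result.metadata, indent=2, sort_keys=True) + "\n")
    return csv_path


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read back a scenario CSV with full float fidelity."""
    return pd.read_csv(path)
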