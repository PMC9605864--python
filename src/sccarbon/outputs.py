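"""Result persistence: draw-level CSV, path arrays as NetCDF, run metadata
as JSON.  Files round-trip losslessly via :func:`load_outputs`."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

SCHEMA_VERSION = 1


def write_outputs(result, out_dir) -> dict:
    """Write an :class:`~sccarbon.valuation.SccResult` to ``out_dir``."""
    if result.draws.empty:
        raise ValueError("refusing to write an empty result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {"draws": out / "scc_draws.csv", "metadata": out / "run_metadata.json"}

    result.draws.to_csv(files["draws"], index=False)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "mean_scc": result.mean,
        "quantiles": {str(k): v for k, v in result.quantiles.items()},
        "near_term_rate_pct": result.near_term_rate_pct,
        "n_failed": result.n_failed,
        **result.metadata,
    }
    files["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))

    if result.paths is not None:
        files["paths"] = out / "paths.nc"
        years = result.paths["years"]
        n_draws = result.paths["temperature"].shape[0]
        ds = xr.Dataset(
            {
                name: (("draw", "year"), np.asarray(result.paths[name]))
                for name in ("temperature", "gsl", "md", "sdf")
            },
            coords={"draw": np.arange(n_draws), "year": years},
            attrs={"schema_version": SCHEMA_VERSION},
        )
        ds.to_netcdf(files["paths"], engine="scipy")
    return files


def load_outputs(out_dir) -> dict:
    out = Path(out_dir)
    loaded = {
        "draws": pd.read_csv(out / "scc_draws.csv"),
        "metadata": json.loads((out / "run_metadata.json").read_text()),
    }
    if loaded["metadata"].get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unrecognized output schema version")
    nc = out / "paths.nc"
    if nc.exists():
        with xr.open_dataset(nc, engine="scipy") as ds:
            loaded["paths"] = ds.load()
    return loaded
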