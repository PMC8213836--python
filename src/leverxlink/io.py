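"""Output writers and the run manifest.

Every stage writes deterministic CSV/JSON artifacts (comma-separated, '.'
decimal, UTF-8, header row) plus a ``manifest.json`` recording parameters,
derived seeds, package version and wall-clock metadata.  Reruns with the same
config produce byte-identical data files; only the manifest timestamp moves.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_outputs"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_outputs(
    results: dict[str, "pd.DataFrame | dict"],
    out_dir: str | Path,
    params: dict | None = None,
    seeds: dict | None = None,
) -> Path:
    """Write result tables/records and a manifest; return the manifest path.

    ``results`` maps file stems to DataFrames (written as ``<stem>.csv``) or
    dicts (written as ``<stem>.json``).  An empty ``results`` writes the
    manifest only.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}: {exc}") from exc

    files = []
    for stem, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{stem}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out_dir / f"{stem}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=2))
        files.append(path.name)

    manifest = {
        "package": "leverxlink",
        "version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(),
        "platform": platform.platform(),
        "files": files,
        "params": _jsonable(params or {}),
        "seeds": _jsonable(seeds or {}),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
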