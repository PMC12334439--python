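"""Rendering of results tables and provenance manifests.

The rendered table mirrors the conventional layout for moderated twin-model
results: variance-component rows first (reported as variances at the average
environment, i.e. ``exp(beta0_X)``), then one ``A x <variable>`` row per
moderation slope, each with a point estimate and 95% HPD interval at two
decimals.  Full precision lives in the posterior CSV, not in the table.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .inference import PosteriorSummary, hpd

__all__ = ["render_table", "write_manifest", "file_digest"]

_VARIANCE_LABELS = {"beta0_A": "β_0A", "beta0_C": "β_0C", "beta0_E": "β_0E"}


def render_table(summary: PosteriorSummary, mass: float = 0.95) -> str:
    """Text table of variance components at E=0 and moderation effects."""
    rows = []
    for name, label in _VARIANCE_LABELS.items():
        if name in summary.draws:
            var_draws = np.exp(summary.flat(name))
            lo, hi = hpd(var_draws, mass)
            rows.append((label, float(var_draws.mean()), lo, hi))
    for mod in summary.config.moderators:
        d = summary.flat(f"beta1_A:{mod}")
        lo, hi = hpd(d, mass)
        rows.append((f"A x {mod}", float(d.mean()), lo, hi))

    header = ("Parameter", "Point estimate", "95% HPD")
    body = [
        (label, f"{est:.2f}", f"[{lo:.2f};{hi:.2f}]") for label, est, lo, hi in rows
    ]
    widths = [max(len(r[i]) for r in [header, *body]) for i in range(3)]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in [header, *body]
    ]
    lines.insert(1, "-" * max(len(line) for line in lines))
    return "\n".join(lines)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seed: int,
    inputs: dict[str, str | Path] | None = None,
    status: str = "ok",
) -> Path:
    """Record what produced an output directory: config hash, seed, package
    version, input digests and a timestamp.  One manifest per directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": int(seed),
        "package_version": __version__,
        "inputs": {
            name: file_digest(path) for name, path in (inputs or {}).items()
        },
        "status": status,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path
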