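"""CSV round-tripping for twin datasets, item parameters and posteriors.

Dataset layout is one row per individual twin:

    family_id, twin_index (1 or 2), zygosity (MZ/DZ),
    item_1 .. item_J, <one column per environment variable>

with missing item answers as empty cells.  Item-parameter tables use the
layout ``item_id, discrimination, t1..t6`` and posterior summaries the
layout ``parameter, mean, median, hpd_low, hpd_high, rhat, ess``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .irt import ItemParameters
from .model_core import TwinPairRecord

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_dataset",
    "read_dataset",
    "write_items",
    "read_items",
]


def records_to_frame(records: Sequence[TwinPairRecord]) -> pd.DataFrame:
    n_items = records[0].items_twin1.size
    env_names = sorted(records[0].env_twin1)
    rows = []
    for rec in records:
        for twin, items, env in (
            (1, rec.items_twin1, rec.env_twin1),
            (2, rec.items_twin2, rec.env_twin2),
        ):
            row = {
                "family_id": rec.family_id,
                "twin_index": twin,
                "zygosity": rec.zygosity,
            }
            row.update({f"item_{j + 1}": items[j] for j in range(n_items)})
            row.update({name: env[name] for name in env_names})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[TwinPairRecord]:
    required = {"family_id", "twin_index", "zygosity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
    item_cols = sorted(
        (c for c in frame.columns if c.startswith("item_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not item_cols:
        raise ValueError("dataset has no item_<j> columns")
    env_cols = [
        c for c in frame.columns if c not in required and c not in item_cols
    ]
    records = []
    for fam, grp in frame.groupby("family_id", sort=False):
        if len(grp) != 2 or set(grp["twin_index"]) != {1, 2}:
            raise ValueError(f"family {fam!r} does not have exactly twins 1 and 2")
        grp = grp.sort_values("twin_index")
        zyg = grp["zygosity"].iloc[0]
        if grp["zygosity"].iloc[1] != zyg:
            raise ValueError(f"family {fam!r} has inconsistent zygosity labels")
        t1, t2 = grp.iloc[0], grp.iloc[1]
        records.append(
            TwinPairRecord(
                family_id=str(fam),
                zygosity=str(zyg),
                items_twin1=t1[item_cols].to_numpy(dtype=float),
                items_twin2=t2[item_cols].to_numpy(dtype=float),
                env_twin1={c: float(t1[c]) for c in env_cols},
                env_twin2={c: float(t2[c]) for c in env_cols},
            )
        )
    return records


def write_dataset(records: Sequence[TwinPairRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_dataset(path: str | Path) -> list[TwinPairRecord]:
    return frame_to_records(pd.read_csv(path))


def write_items(items: Sequence[ItemParameters], path: str | Path) -> None:
    rows = []
    for j, item in enumerate(items):
        row = {"item_id": f"item{j + 1}", "discrimination": item.discrimination}
        row.update(
            {f"t{k + 1}": b for k, b in enumerate(item.thresholds)}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_items(path: str | Path) -> list[ItemParameters]:
    frame = pd.read_csv(path)
    t_cols = sorted(
        (c for c in frame.columns if c.startswith("t") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return [
        ItemParameters(
            discrimination=float(row["discrimination"]),
            thresholds=np.array([row[c] for c in t_cols], dtype=float),
        )
        for _, row in frame.iterrows()
    ]
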