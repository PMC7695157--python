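"""Per-subject covariate tables from delimited text.

Expected layout: one row per subject with a ``subject_id`` column, a
``group`` column, and covariate columns (sleep parameters, psychometric
scores).  Item-level questionnaire columns named ``<scale>_item<k>`` are
summed into a ``<scale>`` score; for the depression inventory (BDI) the two
sleep/wake-related items (16 and 17) are excluded from the sum so that the
score is not inflated by the sleep disorder itself.
"""

from __future__ import annotations

import re

import pandas as pd

#: questionnaire items excluded from sum scores, per scale
EXCLUDED_ITEMS: dict[str, tuple[int, ...]] = {"bdi": (16, 17)}

_ITEM_RE = re.compile(r"^(?P<scale>[a-z0-9]+)_item(?P<num>\d+)$")


def load_covariates(path, sep: str = "\t") -> pd.DataFrame:
    """Read a covariate table, collapsing item columns into sum scores."""
    df = pd.read_csv(path, sep=sep)
    if "subject_id" not in df.columns:
        raise ValueError("covariate table must have a 'subject_id' column")
    items: dict[str, list[str]] = {}
    for col in df.columns:
        m = _ITEM_RE.match(col.lower())
        if m:
            scale = m.group("scale")
            num = int(m.group("num"))
            if num in EXCLUDED_ITEMS.get(scale, ()):
                continue
            items.setdefault(scale, []).append(col)
    for scale, cols in items.items():
        df[scale] = df[cols].sum(axis=1)
    drop = [c for c in df.columns if _ITEM_RE.match(c.lower())]
    return df.drop(columns=drop)
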