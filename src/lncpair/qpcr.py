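"""Relative qPCR quantification by the Livak 2^-ddCT method.

dCT_s = CT(target, s) - CT(reference, s); ddCT_s subtracts the calibrator
group's mean dCT; RQ_s = 2^-ddCT_s. Amplification efficiency is assumed
to be exactly 2. By construction the geometric mean of RQ over the
calibrator group is 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class CtTableError(ValueError):
    pass


REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise CtTableError(f"CT table missing columns {missing}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise CtTableError("CT values must be finite")
    if (ct["ct"].to_numpy(dtype=float) <= 0).any():
        raise CtTableError("CT values must be > 0")
    return ct


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Per-sample relative quantity of ``target`` against ``reference``.

    Returns a frame with columns (sample, group, dct, ddct, rq).
    """
    ct = _validate(ct)
    tgt = ct[ct["gene"] == target].set_index("sample")
    ref = ct[ct["gene"] == reference].set_index("sample")
    if tgt.empty:
        raise CtTableError(f"target gene {target!r} absent from the CT table")
    missing_ref = set(tgt.index) - set(ref.index)
    if missing_ref:
        raise CtTableError(
            f"reference gene {reference!r} missing for samples {sorted(missing_ref)}"
        )
    dct = tgt["ct"].astype(float) - ref.loc[tgt.index, "ct"].astype(float)
    groups = tgt["group"]
    cal = dct[groups == calibrator_group]
    if cal.empty:
        raise CtTableError(f"calibrator group {calibrator_group!r} is empty")
    ddct = dct - cal.mean()
    rq = np.power(2.0, -ddct)
    return pd.DataFrame(
        {"sample": tgt.index, "group": groups.to_numpy(),
         "dct": dct.to_numpy(), "ddct": ddct.to_numpy(), "rq": rq.to_numpy()}
    ).reset_index(drop=True)
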