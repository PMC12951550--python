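"""CNS-oriented ADMET screen over predicted binders.

ADMET probabilities are consumed from an externally produced table, never
computed here.  A compound passes when it is a single connected molecular
entity, its predicted binding free energy is strictly below the per-target
threshold, its blood-brain-barrier penetration probability is strictly above
``bbb_min``, and both P-glycoprotein probabilities are strictly below
``pgp_max``.  All comparisons are strict; the boundaries are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from sheafscreen.repurposing_ml import CompoundRecord, FeaturizationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ADMETRecord:
    """Externally predicted CNS-relevant probabilities for one compound."""

    compound_id: str
    bbb: float
    pgp_sub: float
    pgp_inh: float

    def __post_init__(self) -> None:
        for name in ("bbb", "pgp_sub", "pgp_inh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1] for {self.compound_id}")


@dataclass(frozen=True)
class ScreenPolicy:
    """Per-target affinity cutoff plus the CNS probability rules."""

    delta_g_max: float
    bbb_min: float = 0.70
    pgp_max: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.bbb_min < 1.0 or not 0.0 < self.pgp_max < 1.0:
            raise ValueError("bbb_min and pgp_max must lie in (0, 1)")


def is_multifragment(smiles: str) -> bool:
    """True iff the SMILES encodes more than one connected molecular entity
    (mixtures, salts, ion pairs)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES {smiles!r}")
    return len(Chem.GetMolFrags(mol)) > 1


def read_admet_table(path: str | Path) -> dict[str, ADMETRecord]:
    """CSV with columns id, bbb, pgp_sub, pgp_inh."""
    df = pd.read_csv(path)
    required = {"id", "bbb", "pgp_sub", "pgp_inh"}
    if missing := required - set(df.columns):
        raise ValueError(f"ADMET table missing columns {sorted(missing)}")
    return {
        str(r["id"]): ADMETRecord(
            compound_id=str(r["id"]),
            bbb=float(r["bbb"]),
            pgp_sub=float(r["pgp_sub"]),
            pgp_inh=float(r["pgp_inh"]),
        )
        for r in df.to_dict("records")
    }


def passes_policy(
    delta_g_pred: float, admet: ADMETRecord, policy: ScreenPolicy
) -> bool:
    """The pure per-compound rule (excluding the fragment check)."""
    return (
        delta_g_pred < policy.delta_g_max
        and admet.bbb > policy.bbb_min
        and admet.pgp_sub < policy.pgp_max
        and admet.pgp_inh < policy.pgp_max
    )


def apply_cns_screen(
    compounds: Iterable[CompoundRecord],
    admet: Mapping[str, ADMETRecord],
    policy: ScreenPolicy,
) -> list[CompoundRecord]:
    """Filter predicted binders by the CNS rules; sorted by delta_g ascending.

    Compounds without a prediction or without an ADMET record are excluded and
    logged as unscreenable rather than failing the run.
    """
    passing: list[CompoundRecord] = []
    unscreenable: list[str] = []
    for c in compounds:
        if c.failed or c.delta_g_pred is None:
            unscreenable.append(c.compound_id)
            continue
        rec = admet.get(c.compound_id)
        if rec is None:
            unscreenable.append(c.compound_id)
            continue
        if is_multifragment(c.smiles):
            continue
        if passes_policy(c.delta_g_pred, rec, policy):
            passing.append(c)
    if unscreenable:
        logger.info(
            "apply_cns_screen: %d compounds unscreenable (no prediction or no "
            "ADMET record): %s", len(unscreenable), unscreenable,
        )
    return sorted(passing, key=lambda c: (c.delta_g_pred, c.compound_id))


def screen_report(compounds: Sequence[CompoundRecord],
                  admet: Mapping[str, ADMETRecord]) -> pd.DataFrame:
    """Table mirroring the screening output columns."""
    rows = []
    for c in compounds:
        rec = admet.get(c.compound_id)
        rows.append(
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "delta_g_pred": c.delta_g_pred,
                "bbb": rec.bbb if rec else None,
                "pgp_sub": rec.pgp_sub if rec else None,
                "pgp_inh": rec.pgp_inh if rec else None,
            }
        )
    return pd.DataFrame(rows)
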