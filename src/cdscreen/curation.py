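"""Stability-record curation pipeline with a per-step audit trail.

Raw stability-constant records for small-molecule/cyclodextrin systems are
standardized and filtered in a fixed order:

1. drop records without structural information,
2. parse + canonicalize structures (stereochemistry preserved), impute
   missing conditions to T = 25 degC / pH = 7, convert linear-scale Ks to
   ln(Ks),
3. strip single-atom counter-ions,
4. merge duplicate (guest, CD, T, pH) groups whose ln(Ks) spread is below
   10% of the dataset's ln(Ks) range — discordant groups are removed whole,
5. keep guests with 50 < MW < 500 Da,
6. keep near-ambient conditions (20 <= T <= 30, 5 <= pH <= 8),
7. keep 2 <= ln(Ks) <= 10; values outside are treated as outliers.

Every step logs (records in, removed, merged away, records out) into a
:class:`CurationReport`, and removals carry machine-readable reason codes.
All boundary conventions are exposed through :class:`CurationConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd

from . import chem
from .cd_features import lookup_cd
from .chem import StructureError

logger = logging.getLogger(__name__)

NORMAL_TEMPERATURE_C = 25.0
NORMAL_PH = 7.0


@dataclass
class RawRecord:
    """One un-curated measurement as read from an input table."""

    guest_structure: str | None
    cd_identifier: str
    stability_value: float | None
    stability_scale: str = "ln"  # "ln" or "linear"; explicit flag, never guessed
    temperature: float | None = None
    ph: float | None = None
    source_id: str = ""


@dataclass
class StabilityRecord:
    """One curated guest-CD stability measurement."""

    guest_key: str
    cd_key: str
    ln_ks: float
    temperature: float
    ph: float
    guest_smiles: str = ""
    merged_from: int = 1
    imputed_temperature: bool = False
    imputed_ph: bool = False
    source_id: str = ""


@dataclass
class Rejection:
    reason: str
    source_id: str = ""
    detail: str = ""


@dataclass
class CurationStep:
    step: str
    records_in: int
    records_removed: int
    records_merged: int
    records_out: int


@dataclass
class CurationReport:
    steps: list[CurationStep] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)

    def add(self, step: str, n_in: int, removed: int, merged: int) -> None:
        out = n_in - removed - merged
        assert out >= 0
        self.steps.append(CurationStep(step, n_in, removed, merged, out))

    def step_named(self, name: str) -> CurationStep:
        return next(s for s in self.steps if s.step == name)

    def to_dict(self) -> dict:
        return {
            "steps": [asdict(s) for s in self.steps],
            "rejections": [asdict(r) for r in self.rejections],
        }


@dataclass
class CurationConfig:
    mw_min: float = 50.0
    mw_max: float = 500.0
    mw_inclusive: bool = False  # "greater than 50 / less than 500": strict
    t_min: float = 20.0
    t_max: float = 30.0
    ph_min: float = 5.0
    ph_max: float = 8.0
    lnks_min: float = 2.0
    lnks_max: float = 10.0
    merge_rel_tolerance: float = 0.10
    condition_round: int = 1  # duplicate grouping rounds T/pH to this many decimals


# ---------------------------------------------------------------------------
# single-record operations


def cd_canonical_key(cd_identifier: str) -> str:
    """Registry name when recognised, else canonical structure key."""
    entry = lookup_cd(cd_identifier)
    if entry is not None:
        return entry["name"]
    try:
        _, key, _ = chem.standardize_structure(cd_identifier)
        return key
    except StructureError:
        return cd_identifier.strip()


def standardize_record(raw: RawRecord) -> StabilityRecord | Rejection:
    """Canonicalize one raw record or reject it with a reason code.

    Missing temperature/pH are imputed to normal conditions (25 degC, pH 7);
    a linear-scale stability constant (``stability_scale="linear"``) is
    converted to ln(Ks).  Never raises for malformed data.
    """
    if raw.guest_structure is None or not str(raw.guest_structure).strip():
        return Rejection("missing_structure", raw.source_id)
    if raw.stability_value is None or not math.isfinite(raw.stability_value):
        return Rejection("missing_stability_value", raw.source_id)
    try:
        smiles, guest_key, _ = chem.standardize_structure(raw.guest_structure)
    except StructureError as err:
        return Rejection(err.reason, raw.source_id, str(raw.guest_structure))
    if raw.stability_scale == "linear":
        if raw.stability_value <= 0:
            return Rejection("nonpositive_ks", raw.source_id)
        ln_ks = math.log(raw.stability_value)
    else:
        ln_ks = float(raw.stability_value)
    return StabilityRecord(
        guest_key=guest_key,
        cd_key=cd_canonical_key(raw.cd_identifier),
        ln_ks=ln_ks,
        temperature=NORMAL_TEMPERATURE_C if raw.temperature is None else float(raw.temperature),
        ph=NORMAL_PH if raw.ph is None else float(raw.ph),
        guest_smiles=smiles,
        imputed_temperature=raw.temperature is None,
        imputed_ph=raw.ph is None,
        source_id=raw.source_id,
    )


def strip_counter_ions(structure: str) -> str:
    """Remove single-atom counter-ion components from a structure string.

    Raises :class:`StructureError` if nothing multi-atom remains or the
    structure cannot be parsed.
    """
    mol = chem.strip_counter_ions(chem.parse_structure(structure))
    return chem.canonical_smiles(mol)


# ---------------------------------------------------------------------------
# batch filters


def _mw(record: StabilityRecord) -> float | None:
    try:
        return chem.molecular_weight(chem.parse_structure(record.guest_smiles))
    except StructureError:
        return None


def filter_molecular_weight(
    records: list[StabilityRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[StabilityRecord], list[Rejection]]:
    kept, removed = [], []
    for rec in records:
        mw = _mw(rec)
        if mw is None:
            removed.append(Rejection("mw_incomputable", rec.source_id))
        elif _mw_ok(mw, config):
            kept.append(rec)
        else:
            removed.append(Rejection("mw_out_of_range", rec.source_id, f"{mw:.2f}"))
    return kept, removed


def _mw_ok(mw: float, config: CurationConfig) -> bool:
    if config.mw_inclusive:
        return config.mw_min <= mw <= config.mw_max
    return config.mw_min < mw < config.mw_max


def filter_conditions(
    records: list[StabilityRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[StabilityRecord], list[Rejection]]:
    kept, removed = [], []
    for rec in records:
        if config.t_min <= rec.temperature <= config.t_max and config.ph_min <= rec.ph <= config.ph_max:
            kept.append(rec)
        else:
            removed.append(
                Rejection("conditions_out_of_range", rec.source_id, f"T={rec.temperature} pH={rec.ph}")
            )
    return kept, removed


def filter_outliers(
    records: list[StabilityRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[StabilityRecord], list[Rejection]]:
    kept, removed = [], []
    for rec in records:
        if config.lnks_min <= rec.ln_ks <= config.lnks_max:
            kept.append(rec)
        else:
            removed.append(Rejection("lnks_outlier", rec.source_id, f"{rec.ln_ks:.3f}"))
    return kept, removed


def merge_duplicates(
    records: list[StabilityRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[StabilityRecord], int, list[Rejection]]:
    """Merge duplicate (guest, CD, T, pH) groups; drop discordant groups.

    A group is mergeable when its ln(Ks) spread (max - min) is below
    ``merge_rel_tolerance`` times the ln(Ks) range of the *current* dataset;
    the merged record carries the arithmetic-mean ln(Ks) and
    ``merged_from`` = group size.  Returns (records, n merged away,
    rejections for dropped discordant records).
    """
    if not records:
        return [], 0, []
    lo = min(r.ln_ks for r in records)
    hi = max(r.ln_ks for r in records)
    allowed_spread = config.merge_rel_tolerance * (hi - lo)
    nd = config.condition_round
    groups: dict[tuple, list[StabilityRecord]] = {}
    for rec in records:
        key = (rec.guest_key, rec.cd_key, round(rec.temperature, nd), round(rec.ph, nd))
        groups.setdefault(key, []).append(rec)
    out: list[StabilityRecord] = []
    merged_away = 0
    rejections: list[Rejection] = []
    for key in sorted(groups):
        grp = groups[key]
        if len(grp) == 1:
            out.append(grp[0])
            continue
        vals = [r.ln_ks for r in grp]
        if max(vals) - min(vals) < allowed_spread:
            first = grp[0]
            out.append(
                StabilityRecord(
                    guest_key=first.guest_key,
                    cd_key=first.cd_key,
                    ln_ks=sum(vals) / len(vals),
                    temperature=first.temperature,
                    ph=first.ph,
                    guest_smiles=first.guest_smiles,
                    merged_from=sum(r.merged_from for r in grp),
                    imputed_temperature=all(r.imputed_temperature for r in grp),
                    imputed_ph=all(r.imputed_ph for r in grp),
                    source_id=";".join(r.source_id for r in grp if r.source_id),
                )
            )
            merged_away += len(grp) - 1
        else:
            for r in grp:
                rejections.append(Rejection("discordant_duplicate", r.source_id, f"spread>{allowed_spread:.3f}"))
    return out, merged_away, rejections


# ---------------------------------------------------------------------------
# pipeline


class EmptyDatasetError(RuntimeError):
    pass


def run_curation(
    raws: Iterable[RawRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[StabilityRecord], CurationReport]:
    """Run the full curation workflow; deterministic for a fixed input set.

    Output order is canonical (sorted by record keys) so that shuffled
    inputs produce identical outputs.  Raises :class:`EmptyDatasetError`
    when nothing survives, pointing at the report.
    """
    raws = list(raws)
    report = CurationReport()
    report.add("input", len(raws), 0, 0)

    with_structure, missing = [], []
    for r in raws:
        (with_structure if r.guest_structure and str(r.guest_structure).strip() else missing).append(r)
    report.rejections.extend(Rejection("missing_structure", r.source_id) for r in missing)
    report.add("structure_filter", len(raws), len(missing), 0)

    # standardization also strips counter-ions; parse failures are removed
    # here, all-counter-ion records at the dedicated step that follows
    records: list[StabilityRecord] = []
    std_rejected = ion_rejected = 0
    for raw in with_structure:
        res = standardize_record(raw)
        if isinstance(res, Rejection):
            if res.reason == "no_multi_atom_component":
                ion_rejected += 1
            else:
                std_rejected += 1
            report.rejections.append(res)
            logger.info("removed %s: %s", raw.source_id, res.reason)
        else:
            records.append(res)
    report.add("standardization", len(with_structure), std_rejected, 0)
    report.add("counter_ion_removal", len(records) + ion_rejected, ion_rejected, 0)

    records, merged_away, rej = merge_duplicates(records, config)
    report.rejections.extend(rej)
    report.add("duplicate_merge", len(records) + merged_away + len(rej), len(rej), merged_away)

    for name, fn in (
        ("molecular_weight_filter", filter_molecular_weight),
        ("condition_filter", filter_conditions),
        ("outlier_filter", filter_outliers),
    ):
        records, removed = fn(records, config)
        report.rejections.extend(removed)
        for r in removed:
            logger.info("removed %s: %s", r.source_id, r.reason)
        report.add(name, len(records) + len(removed), len(removed), 0)

    records.sort(key=lambda r: (r.guest_key, r.cd_key, r.temperature, r.ph))
    if not records:
        raise EmptyDatasetError("curation removed every record; inspect the report")
    return records, report


# ---------------------------------------------------------------------------
# tabular I/O


def raw_records_from_frame(df: pd.DataFrame) -> list[RawRecord]:
    """Read raw records from a table with the documented column contract.

    Structure columns: ``guest_smiles`` or ``guest_inchi``; CD columns:
    ``cd_name`` or ``cd_smiles``; value columns: ``ln_ks`` or ``ks``
    (explicit linear scale); optional ``temperature_c``, ``ph``,
    ``source_id``.
    """
    def get(row, *cols):
        for c in cols:
            if c in df.columns and pd.notna(row[c]) and str(row[c]).strip() != "":
                return row[c]
        return None

    raws = []
    for i, row in df.iterrows():
        value, scale = get(row, "ln_ks"), "ln"
        if value is None:
            value, scale = get(row, "ks"), "linear"
        raws.append(
            RawRecord(
                guest_structure=get(row, "guest_smiles", "guest_inchi"),
                cd_identifier=str(get(row, "cd_name", "cd_smiles") or ""),
                stability_value=None if value is None else float(value),
                stability_scale=scale,
                temperature=None if get(row, "temperature_c") is None else float(row["temperature_c"]),
                ph=None if get(row, "ph") is None else float(row["ph"]),
                source_id=str(get(row, "source_id") or f"row{i}"),
            )
        )
    return raws


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
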