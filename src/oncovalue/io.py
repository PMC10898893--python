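"""Readers and writers for trial evidence, adverse-event tables and dosing.

Trial evidence travels as versioned UTF-8 JSON (schema tag
``oncovalue-trial/1``).  Adverse-event tables may alternatively be supplied as
CSV with header ``term,grade_band,arm,frequency``.  Frequencies are stored as
proportions in [0, 1]; a ``frequency_unit`` of ``"percent"`` (JSON top level,
or the ``percent=True`` argument of the CSV reader) converts on load, which
removes the 10-vs-0.10 ambiguity at the boundary thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
from pydantic import ValidationError

from .errors import SchemaValidationError
from .evidence import SCHEMA_VERSION, AdverseEventEntry, ToxicityProfile, TrialEvidence

PathLike = Union[str, Path]


def _pointer(err: ValidationError) -> str:
    loc = err.errors()[0]["loc"]
    return "/" + "/".join(str(p) for p in loc)


def _first_message(err: ValidationError) -> str:
    e = err.errors()[0]
    return f"{e['msg']} at {_pointer(err)}"


def load_trial_evidence(path: PathLike, schema_version: str = SCHEMA_VERSION) -> TrialEvidence:
    """Load and validate a trial-evidence JSON document.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaValidationError
        On a schema-version mismatch or any invariant breach; the error
        carries a JSON pointer to the first failing field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial evidence file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise SchemaValidationError("trial evidence document must be a JSON object", "/")
    declared = doc.pop("schema", schema_version)
    if declared != schema_version:
        raise SchemaValidationError(
            f"schema version mismatch: expected {schema_version!r}, got {declared!r}",
            "/schema",
        )
    unit = doc.pop("frequency_unit", "proportion")
    if unit not in ("proportion", "percent"):
        raise SchemaValidationError(
            f"frequency_unit must be 'proportion' or 'percent', got {unit!r}",
            "/frequency_unit",
        )
    if unit == "percent":
        for arm in ("toxicity_test", "toxicity_comparator"):
            for entry in doc.get(arm, {}).get("entries", []):
                if "frequency" in entry:
                    entry["frequency"] = entry["frequency"] / 100.0
    try:
        return TrialEvidence.model_validate(doc)
    except ValidationError as err:
        raise SchemaValidationError(_first_message(err), _pointer(err)) from err


def write_trial_evidence(trial: TrialEvidence, path: PathLike) -> None:
    """Write a trial as key-sorted JSON; ``load(write(t))`` is the identity."""
    doc = {"schema": SCHEMA_VERSION, **trial.model_dump(mode="json", exclude_none=True)}
    payload = json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n"
    Path(path).write_text(payload, encoding="utf-8")


AE_CSV_COLUMNS = ["term", "grade_band", "arm", "frequency"]


def load_ae_table(path: PathLike, percent: bool = False) -> dict[str, ToxicityProfile]:
    """Read an adverse-event CSV into per-arm toxicity profiles.

    The CSV header is ``term,grade_band,arm,frequency`` with ``arm`` one of
    ``test``/``comparator`` and dot decimal separators.  Returns a mapping
    from arm name to :class:`ToxicityProfile`.
    """
    df = pd.read_csv(path)
    missing = [c for c in AE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaValidationError(f"adverse-event CSV missing columns: {missing}", "/")
    profiles: dict[str, ToxicityProfile] = {}
    for arm, group in df.groupby("arm"):
        if arm not in ("test", "comparator"):
            raise SchemaValidationError(f"unknown arm {arm!r} (use 'test'/'comparator')", "/arm")
        entries = []
        for _, row in group.iterrows():
            freq = float(row["frequency"]) / 100.0 if percent else float(row["frequency"])
            try:
                entries.append(
                    AdverseEventEntry(term=str(row["term"]), grade_band=row["grade_band"], frequency=freq)
                )
            except ValidationError as err:
                raise SchemaValidationError(_first_message(err), _pointer(err)) from err
        profiles[str(arm)] = ToxicityProfile(entries=entries)
    return profiles
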