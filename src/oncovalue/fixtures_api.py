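"""Built-in trial evidence and dosing for the four published comparisons.

Two disease stages are covered, each with one trial per drug: nmCRPC
(PROSPER: enzalutamide; SPARTAN: apalutamide) and mHSPC (ARCHES:
enzalutamide; TITAN: apalutamide).  All numbers are published scorecard
inputs; caveats (a toxicity-score inconsistency in PROSPER, a CI typo in
SPARTAN, synthetic tail-curve proportions) are recorded in fixture metadata
and bonus notes.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import SchemaValidationError
from .evidence import SCHEMA_VERSION, TrialEvidence

FIXTURE_NAMES = ("prosper", "spartan", "arches", "titan")

#: which built-in dosing goes with which trial
TRIAL_REGIMEN = {
    "prosper": "enzalutamide",
    "spartan": "apalutamide",
    "arches": "enzalutamide",
    "titan": "apalutamide",
}


def _read_fixture(name: str) -> dict:
    ref = resources.files("oncovalue.fixtures").joinpath(f"{name}.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def builtin_fixture(name: str) -> TrialEvidence:
    """Return the built-in evidence for one of the four trials."""
    key = name.strip().lower()
    if key not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    doc = _read_fixture(key)
    if doc.pop("schema", None) != SCHEMA_VERSION:
        raise SchemaValidationError(f"fixture {key} has wrong schema version", "/schema")
    return TrialEvidence.model_validate(doc)


def builtin_dosing(regimen: str):
    """Return the built-in :class:`~oncovalue.economics.RegimenDosing`."""
    from .economics import RegimenDosing

    doc = _read_fixture("dosing")
    doc.pop("_metadata", None)
    key = regimen.strip().lower()
    if key not in doc:
        raise KeyError(f"unknown regimen {regimen!r}; available: {', '.join(sorted(doc))}")
    return RegimenDosing.model_validate(doc[key])
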