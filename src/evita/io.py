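"""Reading and writing assessment dossiers (YAML or JSON, versioned schema)."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import yaml
from pydantic import ValidationError

from .model import AssessmentDossier

__all__ = ["load_dossier", "write_dossier", "dossier_to_dict", "fixture_path", "FIXTURE_NAMES"]

#: Worked-example dossiers shipped with the package, one per drug-indication
#: pair: lenalidomide in multiple myeloma, pioglitazone in type-2 diabetes
#: (evaluated on the 2001 and again on the 2005 evidence base), bupropion in
#: major depression, and zoledronic acid in postmenopausal osteoporosis.
FIXTURE_NAMES = (
    "lenalidomide_mm",
    "pioglitazone_dm2_2001",
    "pioglitazone_dm2_2005",
    "bupropion_depression",
    "zoledronic_pmo",
)


class DossierValidationError(ValueError):
    """Raised when a dossier file does not conform to the schema."""


def _format_pydantic_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_dossier(path: Union[str, Path]) -> AssessmentDossier:
    """Load and validate an assessment dossier from a YAML or JSON file.

    The format is chosen by extension (``.json`` -> JSON, anything else is
    parsed as YAML, of which JSON is a subset anyway).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    DossierValidationError
        If the document violates the schema; the message names the
        offending field and rule (unknown enum literals list the
        admissible values).
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise DossierValidationError(f"{path}: cannot parse document: {exc}") from exc
    if not isinstance(data, dict):
        raise DossierValidationError(f"{path}: top level must be a mapping")
    try:
        return AssessmentDossier.model_validate(data)
    except ValidationError as exc:
        raise DossierValidationError(f"{path}: {_format_pydantic_error(exc)}") from exc


def dossier_to_dict(dossier: AssessmentDossier) -> dict:
    """Plain-dict form of a dossier (enums as their string literals)."""
    return dossier.model_dump(mode="json", exclude_none=True)


def write_dossier(dossier: AssessmentDossier, path: Union[str, Path]) -> None:
    """Write a dossier to YAML (default) or JSON, chosen by extension.

    ``load_dossier(write_dossier(d, p))`` round-trips to an equal dossier.
    """
    path = Path(path)
    data = dossier_to_dict(dossier)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled worked-example dossier.

    ``name`` is one of :data:`FIXTURE_NAMES`, with or without the ``.yaml``
    extension.
    """
    stem = name.removesuffix(".yaml")
    if stem not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return Path(str(resources.files("evita").joinpath("fixtures", f"{stem}.yaml")))
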