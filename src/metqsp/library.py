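"""Drug library: per-drug mechanism constants, PK parameters, and regimens.

The packaged library carries the 16-agent panel (7 TKIs, 4 downstream kinase
inhibitors, 5 chemotherapies); users can load their own YAML file with the
same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .network import DrugAction, NetworkError
from .pk import DoseRegimen, PKParameters, reverse_allometric

__all__ = ["DrugRecord", "load_drug_library", "LibraryError"]


class LibraryError(ValueError):
    pass


@dataclass
class DrugRecord:
    name: str
    drug_class: str
    actions: list[DrugAction]
    pk: PKParameters
    default_regimen: DoseRegimen
    reverse_allometric_mouse: bool = False

    def mouse_pk(self) -> PKParameters:
        """Mouse PK, via reverse allometric scaling when flagged."""
        if self.reverse_allometric_mouse:
            return reverse_allometric(self.pk)
        # without a dedicated mouse dataset the same scaling is the default route
        return reverse_allometric(self.pk)

    @property
    def is_met_tki(self) -> bool:
        return any(a.mechanism == "met_tki_binding" for a in self.actions)

    @property
    def is_chemo(self) -> bool:
        return any(a.mechanism == "chemo_cell_kill" for a in self.actions)


def _record_from_dict(name: str, entry: dict) -> DrugRecord:
    for key in ("actions", "pk", "default_regimen"):
        if key not in entry:
            raise LibraryError(f"drug {name!r}: missing field {key!r}")
    try:
        actions = [DrugAction(drug=name, **a) for a in entry["actions"]]
    except (TypeError, NetworkError) as e:
        raise LibraryError(f"drug {name!r}: bad action spec: {e}") from e
    try:
        pk = PKParameters(**entry["pk"])
        regimen = DoseRegimen(**entry["default_regimen"])
    except (TypeError, ValueError) as e:
        raise LibraryError(f"drug {name!r}: bad PK/regimen spec: {e}") from e
    return DrugRecord(
        name=name,
        drug_class=entry.get("class", "unknown"),
        actions=actions,
        pk=pk,
        default_regimen=regimen,
        reverse_allometric_mouse=bool(entry.get("reverse_allometric_mouse", False)),
    )


def load_drug_library(path: str | Path | None = None) -> dict[str, DrugRecord]:
    """Load the drug library from ``path`` (default: the packaged 16-drug panel)."""
    if path is None:
        text = resources.files("metqsp.data").joinpath("drugs.yaml").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise LibraryError(f"drug library file not found: {p}")
        text = p.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise LibraryError("drug library must be a non-empty mapping")
    return {name: _record_from_dict(name, entry) for name, entry in raw.items()}
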