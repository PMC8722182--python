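"""Diagnosis / drug code registries for the RA-ILD algorithms.

Every code set the algorithms consult lives in one :class:`CodeRegistry`:

* ``ild_specific`` — codes specific enough for ILD that their presence in a
  patient's baseline disqualifies a later incident classification.
* ``ild_sensitive`` — broad screen codes (e.g. ICD-9-CM 518.89, "other
  disorders of lung") that catch suspected cases but perform poorly as
  case definitions.
* ``ild_final_algorithm`` — the codes retained by the final case-finding
  algorithm after per-code screening.
* ``sarcoidosis_exclusion`` — ILD mimics excluded during the incident clean
  window (ICD-9-CM 135, ICD-10-CM D86.9 at minimum).
* RA cohort codes (ICD-9-CM 714.0 / 714.2), the seropositive-RA proxy
  family (ICD-10-CM M05), and baseline autoimmune / malignancy exclusions.

Codes are matched after stripping dots (claims extracts vary in dot
formatting).  An entry ending in ``*`` is a family prefix: ``M05*`` matches
``M05.10``.  The autoimmune and malignancy exclusion lists ship as editable
defaults because the source conditions (lupus, scleroderma, myositis,
malignancy except non-melanoma skin cancer, HIV, organ transplant) admit
many codes; registries are fully configuration-driven via YAML.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .model import CodeSystem, DrugClass

CodeEntry = tuple[str, CodeSystem]


class CodeClass(enum.Enum):
    ILD_SPECIFIC = "ild_specific"
    ILD_SENSITIVE = "ild_sensitive"
    SARCOID_EXCLUSION = "sarcoid_exclusion"
    RA = "ra"
    SEROPOSITIVE_RA = "seropositive_ra"
    AUTOIMMUNE_EXCL = "autoimmune_excl"
    MALIGNANCY_EXCL = "malignancy_excl"
    OTHER = "other"


class RegistryError(ValueError):
    """Raised when a registry violates its structural invariants."""


def normalize_code(code: str) -> str:
    """Uppercase and strip dots: ``'j84.10' -> 'J8410'``."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class _CodeSet:
    """A set of (code, system) entries with optional ``*`` family prefixes."""

    exact: frozenset[CodeEntry]
    prefixes: tuple[CodeEntry, ...]

    @classmethod
    def build(cls, entries: Iterable[CodeEntry]) -> "_CodeSet":
        exact, prefixes = set(), []
        for code, system in entries:
            norm = normalize_code(code)
            if norm.endswith("*"):
                prefixes.append((norm[:-1], system))
            else:
                exact.add((norm, system))
        return cls(frozenset(exact), tuple(sorted(prefixes)))

    def __contains__(self, item: CodeEntry) -> bool:
        code, system = item
        norm = normalize_code(code)
        if (norm, system) in self.exact:
            return True
        return any(norm.startswith(p) and system == s for p, s in self.prefixes)

    def entries(self) -> list[CodeEntry]:
        out = [(c, s) for c, s in self.exact]
        out += [(p + "*", s) for p, s in self.prefixes]
        return sorted(out, key=lambda e: (e[1].value, e[0]))

    def __bool__(self) -> bool:
        return bool(self.exact or self.prefixes)


@dataclass(frozen=True)
class CodeRegistry:
    ild_specific: _CodeSet
    ild_sensitive: _CodeSet
    ild_final_algorithm: _CodeSet
    sarcoidosis_exclusion: _CodeSet
    ra_codes: _CodeSet
    seropositive_ra_codes: _CodeSet
    autoimmune_exclusion: _CodeSet
    malignancy_exclusion: _CodeSet
    dmard_names: Mapping[str, DrugClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spec = {e for e in self.ild_specific.entries()}
        sens = {e for e in self.ild_sensitive.entries()}
        overlap = spec & sens
        if overlap:
            raise RegistryError(f"codes in both ild_specific and ild_sensitive: {sorted(overlap)}")
        for entry in self.ild_final_algorithm.entries():
            code, system = entry
            probe = (code.rstrip("*"), system)
            if probe not in self.ild_specific and probe not in self.ild_sensitive:
                raise RegistryError(
                    f"final-algorithm code {entry} not in ild_specific or ild_sensitive"
                )
        for required in [("135", CodeSystem.ICD9CM), ("D86.9", CodeSystem.ICD10CM)]:
            if required not in self.sarcoidosis_exclusion:
                raise RegistryError(f"sarcoidosis_exclusion must contain {required}")

    def classify(self, code: str, system: CodeSystem) -> CodeClass:
        """Deterministic class of a code; exclusion classes take precedence.

        Precedence (highest first): autoimmune exclusion, malignancy
        exclusion, sarcoidosis exclusion, then seropositive RA before plain
        RA (M05 is the more informative label), then specific before
        sensitive ILD.  A code in no set classifies as ``OTHER``.
        """
        entry = (code, system)
        if entry in self.autoimmune_exclusion:
            return CodeClass.AUTOIMMUNE_EXCL
        if entry in self.malignancy_exclusion:
            return CodeClass.MALIGNANCY_EXCL
        if entry in self.sarcoidosis_exclusion:
            return CodeClass.SARCOID_EXCLUSION
        if entry in self.seropositive_ra_codes:
            return CodeClass.SEROPOSITIVE_RA
        if entry in self.ra_codes:
            return CodeClass.RA
        if entry in self.ild_specific:
            return CodeClass.ILD_SPECIFIC
        if entry in self.ild_sensitive:
            return CodeClass.ILD_SENSITIVE
        return CodeClass.OTHER

    # convenience predicates used throughout the algorithms
    def is_ild_screen(self, code: str, system: CodeSystem) -> bool:
        return (code, system) in self.ild_specific or (code, system) in self.ild_sensitive

    def is_ild_final(self, code: str, system: CodeSystem) -> bool:
        return (code, system) in self.ild_final_algorithm

    def is_ra(self, code: str, system: CodeSystem) -> bool:
        return (code, system) in self.ra_codes or (code, system) in self.seropositive_ra_codes

    def is_seropositive_proxy(self, code: str, system: CodeSystem) -> bool:
        return (code, system) in self.seropositive_ra_codes

    def is_incident_disqualifier(self, code: str, system: CodeSystem) -> bool:
        """Codes whose clean-window presence blocks an incident classification:
        specific ILD plus sarcoidosis; sensitive codes do not disqualify."""
        return (code, system) in self.ild_specific or (code, system) in self.sarcoidosis_exclusion

    def is_baseline_exclusion(self, code: str, system: CodeSystem) -> bool:
        return (code, system) in self.autoimmune_exclusion or (
            (code, system) in self.malignancy_exclusion
        )

    def to_dict(self) -> dict:
        def dump(cs: _CodeSet) -> dict[str, list[str]]:
            out: dict[str, list[str]] = {}
            for code, system in cs.entries():
                out.setdefault(system.value, []).append(code)
            return out

        return {
            "ild_specific": dump(self.ild_specific),
            "ild_sensitive": dump(self.ild_sensitive),
            "ild_final_algorithm": dump(self.ild_final_algorithm),
            "sarcoidosis_exclusion": dump(self.sarcoidosis_exclusion),
            "ra_codes": dump(self.ra_codes),
            "seropositive_ra_codes": dump(self.seropositive_ra_codes),
            "autoimmune_exclusion": dump(self.autoimmune_exclusion),
            "malignancy_exclusion": dump(self.malignancy_exclusion),
            "dmard_names": {name: cls.value for name, cls in sorted(self.dmard_names.items())},
        }

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# default registry


def _entries(mapping: Mapping[str, Iterable[str]]) -> list[CodeEntry]:
    return [(code, CodeSystem(system)) for system, codes in mapping.items() for code in codes]


# Final case-finding code set: specific ILD codes retained after per-code
# PPV screening (post-inflammatory pulmonary fibrosis, idiopathic pulmonary
# fibrosis, RB-ILD, other alveolar pneumonopathies, rheumatoid lung).
_FINAL_ILD = {
    "ICD9CM": ["515", "516.31", "516.34", "516.8", "714.81"],
    "ICD10CM": ["J84.10", "J84.112", "J84.9", "M05.10"],
}

# Broad-screen sensitive codes: catch suspected ILD but have poor PPV
# (bronchiectasis, other lung disorders, nonspecific imaging findings,
# unspecified chronic bronchitis / pneumonia) — used only for screening
# and sensitivity denominators, never as the case definition.
_SENSITIVE_ILD = {
    "ICD9CM": ["494.0", "518.89", "793.19", "491.9"],
    "ICD10CM": ["J47.9", "J98.4", "R91.8", "J42", "J18.9"],
}

_SARCOID = {"ICD9CM": ["135"], "ICD10CM": ["D86.9"]}

_RA = {"ICD9CM": ["714.0", "714.2"]}
_SEROPOSITIVE_RA = {"ICD10CM": ["M05*"]}

# Editable defaults; the target conditions are named by the cohort rules but
# any concrete list is a coding-practice choice.
_AUTOIMMUNE = {
    "ICD9CM": ["710.0", "710.1", "710.3", "710.4", "042", "V42*"],
    "ICD10CM": ["M32*", "M34*", "M33*", "B20", "Z94*"],
}
_MALIGNANCY = {
    # ICD-9 140-172 and 174-208 are malignant neoplasms; 173 (non-melanoma
    # skin cancer) is deliberately absent.
    "ICD9CM": [f"{i}*" for i in range(140, 173)] + [f"{i}*" for i in range(174, 209)],
    "ICD10CM": [f"C{i:02d}*" for i in list(range(0, 44)) + list(range(45, 97))],
}

#: RA medications satisfying the treatment requirement.
_DMARDS: dict[str, DrugClass] = {
    "hydroxychloroquine": DrugClass.CSDMARD,
    "sulfasalazine": DrugClass.CSDMARD,
    "methotrexate": DrugClass.CSDMARD,
    "leflunomide": DrugClass.CSDMARD,
    "infliximab": DrugClass.BDMARD,
    "etanercept": DrugClass.BDMARD,
    "adalimumab": DrugClass.BDMARD,
    "golimumab": DrugClass.BDMARD,
    "certolizumab pegol": DrugClass.BDMARD,
    "abatacept": DrugClass.BDMARD,
    "tocilizumab": DrugClass.BDMARD,
    "rituximab": DrugClass.BDMARD,
    "tofacitinib": DrugClass.TSDMARD,
}


def default_registry() -> CodeRegistry:
    """The built-in registry: final ILD codes as the specific set, broad
    screen codes as the sensitive set, sarcoid exclusions, RA cohort codes,
    the M05 seropositivity proxy family, and editable baseline exclusions."""
    return CodeRegistry(
        ild_specific=_CodeSet.build(_entries(_FINAL_ILD)),
        ild_sensitive=_CodeSet.build(_entries(_SENSITIVE_ILD)),
        ild_final_algorithm=_CodeSet.build(_entries(_FINAL_ILD)),
        sarcoidosis_exclusion=_CodeSet.build(_entries(_SARCOID)),
        ra_codes=_CodeSet.build(_entries(_RA)),
        seropositive_ra_codes=_CodeSet.build(_entries(_SEROPOSITIVE_RA)),
        autoimmune_exclusion=_CodeSet.build(_entries(_AUTOIMMUNE)),
        malignancy_exclusion=_CodeSet.build(_entries(_MALIGNANCY)),
        dmard_names=dict(_DMARDS),
    )


_SET_KEYS = [
    "ild_specific",
    "ild_sensitive",
    "ild_final_algorithm",
    "sarcoidosis_exclusion",
    "ra_codes",
    "seropositive_ra_codes",
    "autoimmune_exclusion",
    "malignancy_exclusion",
]


def load_code_registry(config: str | Path | Mapping | None = None) -> CodeRegistry:
    """Load a registry from a YAML file / mapping, or the built-in default.

    ``config`` may be ``None`` or ``"default"`` (built-in defaults), a path
    to a YAML file, or an already-parsed mapping with the same shape as
    :meth:`CodeRegistry.to_dict`.  Structural invariants (disjoint
    specific/sensitive sets, final set covered, mandatory sarcoid codes)
    are enforced on load.
    """
    if config is None or config == "default":
        return default_registry()
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, Mapping):
        raise RegistryError("registry config must be a mapping")
    kwargs = {}
    for key in _SET_KEYS:
        kwargs[key] = _CodeSet.build(_entries(config.get(key, {})))
    dmards = {
        str(name): DrugClass(cls) for name, cls in (config.get("dmard_names") or {}).items()
    }
    return CodeRegistry(dmard_names=dmards, **kwargs)
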