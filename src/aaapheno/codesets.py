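"""Named, configurable code sets driving the classification rules.

Six roles are required by the rule cascade:

- ``aaa_dx`` — ICD-9 diagnosis codes for AAA (441.3 ruptured, 441.4 without
  rupture), the union of the two sets below;
- ``aaa_ruptured_dx`` / ``aaa_unruptured_dx`` — the rupture split;
- ``aaa_repair_px`` — CPT codes for open and endovascular AAA repair;
- ``phenocopy_exclusion_dx`` — heritable disorders with aneurysm
  manifestation (Marfan, Ehlers-Danlos, Moyamoya, fibromuscular dysplasia)
  plus other aortic aneurysm/dissection codes (phenocopies of
  non-syndromic AAA);
- ``control_exclusion_dx`` — the ``441.*`` wildcard: any aortic-aneurysm
  code bars a subject from the control group.

The shipped defaults cover the codes that are uncontroversial in the ICD-9
vocabulary; the repair-CPT list and the tail of the phenocopy list are
site-configurable and should be audited against the site's own billing
practice before production use (see README).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .model import CodePattern, CodingSystem, code_matches, normalize_cpt, normalize_icd9

__all__ = [
    "CodeSet",
    "CodeSetRegistry",
    "ConfigError",
    "ROLE_SYSTEMS",
    "default_registry",
    "load_registry",
    "registry_from_mapping",
]


class ConfigError(ValueError):
    """A code-set configuration is invalid."""


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """A named collection of literal codes and wildcard patterns."""

    name: str
    system: CodingSystem
    members: frozenset[CodePattern]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"code set {self.name!r} has no members")
        wrong = {m.pattern for m in self.members if m.system is not self.system}
        if wrong:
            raise ConfigError(
                f"code set {self.name!r} ({self.system.value}) contains members "
                f"of another system: {sorted(wrong)}"
            )
        # precompiled lookups for fast matching
        object.__setattr__(
            self, "_literals",
            frozenset(m.pattern for m in self.members if not m.is_wildcard),
        )
        object.__setattr__(
            self, "_wildcards",
            tuple(m for m in self.members if m.is_wildcard),
        )

    def matches(self, code: str) -> bool:
        """True if a normalized code is matched by any member pattern."""
        if code in self._literals:
            return True
        return any(code_matches(w, code) for w in self._wildcards)

    def match_series(self, codes: pd.Series) -> pd.Series:
        """Vectorized :meth:`matches` over a Series of normalized codes."""
        return codes.map(self.matches)

    @property
    def patterns(self) -> tuple[str, ...]:
        return tuple(sorted(m.pattern for m in self.members))


#: Role name -> coding system of that role.
ROLE_SYSTEMS: dict[str, CodingSystem] = {
    "aaa_dx": CodingSystem.ICD9,
    "aaa_ruptured_dx": CodingSystem.ICD9,
    "aaa_unruptured_dx": CodingSystem.ICD9,
    "aaa_repair_px": CodingSystem.CPT,
    "phenocopy_exclusion_dx": CodingSystem.ICD9,
    "control_exclusion_dx": CodingSystem.ICD9,
}


@dataclasses.dataclass(frozen=True)
class CodeSetRegistry:
    """The six code sets required by the classification cascade."""

    aaa_dx: CodeSet
    aaa_ruptured_dx: CodeSet
    aaa_unruptured_dx: CodeSet
    aaa_repair_px: CodeSet
    phenocopy_exclusion_dx: CodeSet
    control_exclusion_dx: CodeSet

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for role, system in ROLE_SYSTEMS.items():
            cs = getattr(self, role)
            if cs.system is not system:
                raise ConfigError(
                    f"role {role!r} must use {system.value}, got {cs.system.value}"
                )
        union = {m.pattern for m in self.aaa_ruptured_dx.members} | {
            m.pattern for m in self.aaa_unruptured_dx.members
        }
        whole = {m.pattern for m in self.aaa_dx.members}
        if union != whole:
            raise ConfigError(
                "aaa_ruptured_dx ∪ aaa_unruptured_dx must equal aaa_dx "
                f"({sorted(union)} vs {sorted(whole)})"
            )
        for m in self.aaa_dx.members:
            probe = m.prefix if m.is_wildcard else m.pattern
            if not self.control_exclusion_dx.matches(probe):
                raise ConfigError(
                    f"aaa_dx member {m.pattern!r} is not covered by "
                    "control_exclusion_dx; controls could carry AAA codes"
                )

    def as_dict(self) -> dict[str, dict[str, object]]:
        """Role -> {system, members} mapping (config echo / serialization)."""
        return {
            role: {
                "system": getattr(self, role).system.value,
                "members": list(getattr(self, role).patterns),
            }
            for role in ROLE_SYSTEMS
        }


def _icd9_set(name: str, patterns: Iterable[str]) -> CodeSet:
    members = []
    for p in patterns:
        if p.endswith(".*"):
            members.append(
                CodePattern(CodingSystem.ICD9, normalize_icd9(p[:-2]) + ".*")
            )
        else:
            members.append(CodePattern(CodingSystem.ICD9, normalize_icd9(p)))
    return CodeSet(name, CodingSystem.ICD9, frozenset(members))


def _cpt_set(name: str, patterns: Iterable[str]) -> CodeSet:
    members = [CodePattern(CodingSystem.CPT, normalize_cpt(p)) for p in patterns]
    return CodeSet(name, CodingSystem.CPT, frozenset(members))


# Heritable disorders with aneurysm manifestation, plus other aortic
# aneurysm / dissection codes (phenocopies of non-syndromic AAA).
_PHENOCOPY_DEFAULT = (
    "759.82",  # Marfan syndrome
    "756.83",  # Ehlers-Danlos syndrome
    "437.5",   # Moyamoya disease
    "447.8",   # fibromuscular dysplasia (other specified arterial disease)
    "441.00", "441.01", "441.02", "441.03",  # aortic dissection by site
    "441.1",   # thoracic aneurysm, ruptured
    "441.2",   # thoracic aneurysm w/o rupture
    "441.5",   # aortic rupture, unspecified site
    "441.6",   # thoracoabdominal aneurysm, ruptured
    "441.7",   # thoracoabdominal aneurysm w/o rupture
    "441.9",   # aortic aneurysm, unspecified
)

# Default open + endovascular AAA-repair CPT codes.  Site-configurable: the
# billing codes actually used vary by site and era, so audit this list
# against local practice (the engine only ever tests set membership).
_REPAIR_CPT_DEFAULT = (
    "34800", "34802", "34803", "34804", "34805",  # EVAR, by graft type
    "34825", "34826",                              # EVAR extension modules
    "34830", "34831", "34832",                     # open repair after failed EVAR
    "35081", "35082",                              # direct open repair (ruptured: 35082)
    "35091", "35092",                              # open repair involving visceral vessels
    "35102", "35103",                              # open repair involving iliac vessels
)


def default_registry() -> CodeSetRegistry:
    """The shipped default registry.

    Pure: repeated calls return equal registries.
    """
    return CodeSetRegistry(
        aaa_dx=_icd9_set("aaa_dx", ("441.3", "441.4")),
        aaa_ruptured_dx=_icd9_set("aaa_ruptured_dx", ("441.3",)),
        aaa_unruptured_dx=_icd9_set("aaa_unruptured_dx", ("441.4",)),
        aaa_repair_px=_cpt_set("aaa_repair_px", _REPAIR_CPT_DEFAULT),
        phenocopy_exclusion_dx=_icd9_set(
            "phenocopy_exclusion_dx", _PHENOCOPY_DEFAULT
        ),
        control_exclusion_dx=_icd9_set("control_exclusion_dx", ("441.*",)),
    )


def registry_from_mapping(config: Mapping[str, object]) -> CodeSetRegistry:
    """Build a registry from a role -> spec mapping, on top of the defaults.

    Each role block may contain ``system`` (must match the role), ``members``
    (replaces the default member list) and/or ``extra_members`` (extends it).
    """
    base = default_registry()
    if not config:
        return base
    overrides: dict[str, CodeSet] = {}
    for role, block in config.items():
        if role not in ROLE_SYSTEMS:
            raise ConfigError(
                f"unknown code-set role {role!r}; valid roles: "
                + ", ".join(sorted(ROLE_SYSTEMS))
            )
        if not isinstance(block, Mapping):
            raise ConfigError(f"role {role!r}: expected a mapping")
        system = ROLE_SYSTEMS[role]
        declared = block.get("system")
        if declared is not None and str(declared).upper() != system.value:
            raise ConfigError(
                f"role {role!r} requires system {system.value}, got {declared!r}"
            )
        members = block.get("members")
        extra = block.get("extra_members", [])
        if members is None:
            patterns = list(getattr(base, role).patterns)
        else:
            patterns = [str(p) for p in members]
        patterns += [str(p) for p in extra]
        if not patterns:
            raise ConfigError(f"role {role!r}: empty member list")
        build = _icd9_set if system is CodingSystem.ICD9 else _cpt_set
        try:
            overrides[role] = build(role, patterns)
        except ValueError as exc:
            raise ConfigError(f"role {role!r}: {exc}") from exc
    fields = {role: overrides.get(role, getattr(base, role)) for role in ROLE_SYSTEMS}
    return CodeSetRegistry(**fields)


def load_registry(config_path) -> CodeSetRegistry:
    """Load a registry from a YAML/JSON config file.

    The file may hold the role mapping at top level or under a ``code_sets``
    key; roles omitted from the file keep their defaults.
    """
    with open(config_path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return default_registry()
    if not isinstance(data, Mapping):
        raise ConfigError(f"{config_path}: expected a mapping at top level")
    if "code_sets" in data:
        block = data["code_sets"] or {}
    else:
        # bare role mapping at top level; other config sections are ignored
        block = {k: v for k, v in data.items() if k not in ("engine", "columns")}
    return registry_from_mapping(block)
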