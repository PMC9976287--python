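"""YAML job configuration.

Schema (keys beyond these are rejected)::

    input_cores:                # list; str path or {path, anchor}
      - path: core.xyz
        anchor: A               # symbol or list of 0-based indices
    input_ligands:              # list of SMILES strings or structure paths
      - "CC(=O)O"
    optional:
      core:
        anchor: Cl              # default scaffold anchor element
      ligand:
        anchor:                 # functional-group specs; omit for built-ins
          - {group: "[SX2H]", anchor_idx: 0, remove_idx: [], split: true}
        split: true             # global override for user-given groups
      distribution:
        mode: uniform           # uniform | cluster | random, or
                                # [[mode, count], ...] mixture stages
        fraction: 0.5           # exactly one of fraction / count
        count: 10
        distance: through_space # or over_surface
        weight_exponent: 1.0    # f(x) = exp(-weight_exponent * x)
      alignment: surface        # surface | sphere_invert | covalent
      multi_ligand:             # one pass, several dummy -> ligand maps
        - {dummy: A, ligand: "CC[NH3+]"}
    output: {format: xyz, dir: output}
    seed: 42
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anchors import DEFAULT_GROUPS, FunctionalGroupSpec

__all__ = ["JobConfig", "CoreSpec", "DistributionSpec", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """The job configuration is missing, contradictory, or malformed."""


@dataclass(frozen=True)
class CoreSpec:
    path: str
    anchor: str | tuple[int, ...] | None = None  # falls back to JobConfig.core_anchor


@dataclass(frozen=True)
class DistributionSpec:
    """How the anchor superset is reduced to the passivated subset."""

    mode: str | tuple[tuple[str, int], ...] = "uniform"
    fraction: float | None = None
    count: int | None = None
    distance: str = "through_space"
    weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.fraction is not None and self.count is not None:
            raise ConfigError("set exactly one of distribution.fraction / distribution.count")
        if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
            raise ConfigError(f"distribution.fraction must be in (0, 1], got {self.fraction}")
        if self.count is not None and self.count < 1:
            raise ConfigError(f"distribution.count must be >= 1, got {self.count}")
        if self.distance not in ("through_space", "over_surface"):
            raise ConfigError(f"unknown distribution.distance {self.distance!r}")
        if isinstance(self.mode, str):
            if self.mode not in ("uniform", "cluster", "random"):
                raise ConfigError(f"unknown distribution.mode {self.mode!r}")
        else:
            for m, k in self.mode:
                if m not in ("uniform", "cluster", "random"):
                    raise ConfigError(f"unknown mixture stage mode {m!r}")
                if k < 1:
                    raise ConfigError(f"mixture stage count must be >= 1, got {k}")

    def resolve_count(self, n_anchors: int) -> int:
        """Number of sites to keep out of ``n_anchors`` (full set if unset)."""
        if self.count is not None:
            return min(self.count, n_anchors)
        frac = 1.0 if self.fraction is None else self.fraction
        return max(1, min(n_anchors, int(frac * n_anchors + 0.5)))


@dataclass
class JobConfig:
    input_cores: list[CoreSpec]
    input_ligands: list[str]
    core_anchor: str | tuple[int, ...] = "Cl"
    ligand_groups: tuple[FunctionalGroupSpec, ...] = DEFAULT_GROUPS
    split: bool | None = None  # None: per-group default
    distribution: DistributionSpec = field(default_factory=DistributionSpec)
    alignment: str = "surface"
    multi_ligand: tuple[tuple[str, str], ...] = ()  # (dummy symbol, ligand SMILES/path)
    output_format: str = "xyz"
    output_dir: str = "output"
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.input_cores:
            raise ConfigError("input_cores must list at least one scaffold")
        if not self.input_ligands and not self.multi_ligand:
            raise ConfigError("input_ligands must list at least one ligand")
        if self.alignment not in ("surface", "sphere_invert", "covalent"):
            raise ConfigError(f"unknown alignment {self.alignment!r}")
        if self.output_format not in ("xyz", "pdb"):
            raise ConfigError(f"unknown output format {self.output_format!r}")


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {where}")


def _parse_anchor(value) -> str | tuple[int, ...]:
    if isinstance(value, str):
        return value
    if isinstance(value, (list, tuple)) and all(isinstance(v, int) for v in value):
        return tuple(value)
    raise ConfigError(f"anchor must be an element symbol or an index list, got {value!r}")


def _parse_core(entry) -> CoreSpec:
    if isinstance(entry, str):
        return CoreSpec(path=entry)
    if isinstance(entry, dict):
        _reject_unknown(entry, {"path", "anchor"}, "input_cores[]")
        if "path" not in entry:
            raise ConfigError("each input_cores entry needs a 'path'")
        anchor = _parse_anchor(entry["anchor"]) if "anchor" in entry else None
        return CoreSpec(path=str(entry["path"]), anchor=anchor)
    raise ConfigError(f"bad input_cores entry: {entry!r}")


def _parse_group(entry, global_split: bool | None) -> FunctionalGroupSpec:
    if isinstance(entry, str):
        try:
            from .anchors import builtin_group

            g = builtin_group(entry)
        except KeyError:
            g = FunctionalGroupSpec(pattern=entry)
        if global_split is not None:
            g = FunctionalGroupSpec(g.pattern, g.anchor_idx, g.remove_idx, global_split, g.name)
        return g
    if isinstance(entry, dict):
        _reject_unknown(entry, {"group", "anchor_idx", "remove_idx", "split", "name"}, "ligand.anchor[]")
        if "group" not in entry:
            raise ConfigError("each ligand.anchor entry needs a 'group' pattern")
        split = entry.get("split", True if global_split is None else global_split)
        return FunctionalGroupSpec(
            pattern=str(entry["group"]),
            anchor_idx=int(entry.get("anchor_idx", 0)),
            remove_idx=tuple(entry.get("remove_idx", ())),
            split=bool(split),
            name=str(entry.get("name", "")),
        )
    raise ConfigError(f"bad ligand.anchor entry: {entry!r}")


def _parse_distribution(d: dict) -> DistributionSpec:
    _reject_unknown(d, {"mode", "fraction", "count", "distance", "weight_exponent"}, "optional.distribution")
    mode = d.get("mode", "uniform")
    if isinstance(mode, (list, tuple)):
        mode = tuple((str(m), int(k)) for m, k in mode)
    return DistributionSpec(
        mode=mode,
        fraction=d.get("fraction"),
        count=d.get("count"),
        distance=d.get("distance", "through_space"),
        weight_exponent=float(d.get("weight_exponent", 1.0)),
    )


def load_config(path: str | Path) -> JobConfig:
    """Parse and validate a YAML job file into a :class:`JobConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> JobConfig:
    _reject_unknown(raw, {"input_cores", "input_ligands", "optional", "output", "seed"}, "top level")
    if "input_cores" not in raw:
        raise ConfigError("missing required key input_cores")
    if "input_ligands" not in raw and not (raw.get("optional", {}) or {}).get("multi_ligand"):
        raise ConfigError("missing required key input_ligands")
    cores = [_parse_core(e) for e in _as_list(raw["input_cores"], "input_cores")]
    ligands = [str(e) for e in _as_list(raw.get("input_ligands", []), "input_ligands", allow_empty=True)]

    opt = raw.get("optional") or {}
    _reject_unknown(opt, {"core", "ligand", "distribution", "alignment", "multi_ligand"}, "optional")
    core_opt = opt.get("core") or {}
    _reject_unknown(core_opt, {"anchor"}, "optional.core")
    core_anchor = _parse_anchor(core_opt.get("anchor", "Cl"))

    lig_opt = opt.get("ligand") or {}
    _reject_unknown(lig_opt, {"anchor", "split"}, "optional.ligand")
    global_split = lig_opt.get("split")
    if "anchor" in lig_opt:
        groups = tuple(_parse_group(e, global_split) for e in _as_list(lig_opt["anchor"], "ligand.anchor"))
    elif global_split is not None:
        groups = tuple(
            FunctionalGroupSpec(g.pattern, g.anchor_idx, g.remove_idx, bool(global_split), g.name)
            for g in DEFAULT_GROUPS
        )
    else:
        groups = DEFAULT_GROUPS

    dist = _parse_distribution(opt.get("distribution") or {})

    ml = []
    for entry in _as_list(opt.get("multi_ligand", []), "optional.multi_ligand", allow_empty=True):
        if not isinstance(entry, dict):
            raise ConfigError(f"bad multi_ligand entry: {entry!r}")
        _reject_unknown(entry, {"dummy", "ligand"}, "optional.multi_ligand[]")
        if "dummy" not in entry or "ligand" not in entry:
            raise ConfigError("each multi_ligand entry needs 'dummy' and 'ligand'")
        ml.append((str(entry["dummy"]), str(entry["ligand"])))

    out = raw.get("output") or {}
    _reject_unknown(out, {"format", "dir", "path"}, "output")

    return JobConfig(
        input_cores=cores,
        input_ligands=ligands,
        core_anchor=core_anchor,
        ligand_groups=groups,
        split=global_split,
        distribution=dist,
        alignment=str(opt.get("alignment", "surface")),
        multi_ligand=tuple(ml),
        output_format=str(out.get("format", "xyz")),
        output_dir=str(out.get("dir", out.get("path", "output"))),
        seed=int(raw.get("seed", 42)),
    )


def _as_list(value, where: str, allow_empty: bool = False) -> list:
    if value is None:
        value = []
    if not isinstance(value, list):
        value = [value]
    if not value and not allow_empty:
        raise ConfigError(f"{where} must not be empty")
    return value
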