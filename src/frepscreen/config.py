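"""YAML config loading with strict key validation for the CLI.

Every subcommand's knobs mirror a dataclass; unknown keys are rejected by
name, ``--set key=value`` overrides are type-coerced against the dataclass
field types, and the resolved configuration is written next to the outputs
so that every run is reproducible from its artifacts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Type, TypeVar, get_args, get_origin

import yaml

T = TypeVar("T")


def _coerce(value: Any, annotation: Any) -> Any:
    origin = get_origin(annotation)
    if origin is not None:
        # Optional[X] and friends: try the non-None member
        args = [a for a in get_args(annotation) if a is not type(None)]
        if value is None:
            return None
        if len(args) == 1:
            return _coerce(value, args[0])
        return value
    if annotation in (int, float):
        return annotation(value)
    if annotation is bool:
        if isinstance(value, bool):
            return value
        text = str(value).strip().lower()
        if text in ("true", "1", "yes"):
            return True
        if text in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot interpret {value!r} as a boolean")
    if annotation is str:
        return str(value)
    return value


def load_section(cls: Type[T], config_path: str | Path | None,
                 overrides: tuple[str, ...] = ()) -> T:
    """Build a config dataclass from an optional YAML file plus overrides.

    Unknown keys fail loudly by name; ``overrides`` entries look like
    ``key=value`` and win over the file.
    """
    data: dict[str, Any] = {}
    if config_path is not None:
        loaded = yaml.safe_load(Path(config_path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {config_path} must be a YAML mapping")
        data.update(loaded)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like key=value")
        key, _, raw = item.partition("=")
        data[key.strip()] = yaml.safe_load(raw)

    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = [k for k in data if k not in fields]
    if unknown:
        raise ValueError(f"unknown config key {unknown[0]!r} (valid: {sorted(fields)})")
    resolver = dataclasses.fields(cls)
    kwargs: dict[str, Any] = {}
    for f in resolver:
        if f.name in data:
            try:
                kwargs[f.name] = _coerce(data[f.name], f.type if not isinstance(f.type, str) else _annotation_of(cls, f.name))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config key {f.name!r}: {exc}") from None
    return cls(**kwargs)


def _annotation_of(cls: type, name: str) -> Any:
    import typing

    hints = typing.get_type_hints(cls)
    return hints.get(name, str)


def dump_resolved(obj: Any, path: str | Path) -> None:
    """Write a dataclass (or mapping) as YAML next to the run's outputs."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        data = dataclasses.asdict(obj)
    else:
        data = dict(obj)
    clean = {}
    for key, value in data.items():
        if hasattr(value, "item"):
            value = value.item()
        clean[key] = value
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=True))
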