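"""Shared I/O: FASTA reading, run configuration, provenance headers.

Parsing is strict throughout: unknown configuration keys, duplicate record
ids, and ambiguity codes are errors, not warnings, so that long parameter
sweeps fail fast on typos rather than silently drifting.
"""

from __future__ import annotations

import difflib
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml
from Bio import SeqIO

from .energy import ALPHABET, EnergyParameterSet, NucleotideSequence, load_parameters
from .predict import (
    InteractionConstraintSet,
    PredictionConfig,
    SeedConstraintSet,
    preset,
)


class DataError(ValueError):
    """Invalid input data (exit code 2 on the command line)."""


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a DNA/RNA FASTA file into normalized RNA sequences.

    T becomes U, lowercase is uppercased; duplicate ids, empty files and
    IUPAC ambiguity codes (including N) are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: empty or not a FASTA file")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("T", "U")
        bad = sorted(set(residues) - set(ALPHABET))
        if bad:
            raise DataError(
                f"{path}: record {rec.id!r} contains non-ACGT/U characters "
                f"({', '.join(bad)}); ambiguity codes are not supported"
            )
        try:
            out.append(NucleotideSequence(rec.id, residues,
                                          description=rec.description))
        except ValueError as exc:
            raise DataError(f"{path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# run configuration

#: every recognized prediction-parameter key, with its target attribute
_CONFIG_KEYS = {
    "preset": str,
    "energy": str,
    "seedRequired": bool,
    "seedBP": int,
    "allowGU": bool,
    "seedMaxE": float,
    "seedMaxEhybrid": float,
    "seedMinPu": float,
    "intLenMax": int,
    "intMaxE": float,
    "intMinPu": float,
    "maxLoop": int,
}


@dataclass
class RunConfig:
    """Fully resolved run settings for one CLI invocation."""

    subcommand: str
    inputs: dict[str, Path]
    prediction: PredictionConfig
    resolved: dict[str, Any]
    outdir: Optional[Path] = None
    verbosity: int = 0


def _coerce(key: str, value: Any) -> Any:
    typ = _CONFIG_KEYS[key]
    if value is None:
        return None
    if typ is bool:
        if isinstance(value, bool):
            return value
        if str(value).lower() in ("true", "1", "yes"):
            return True
        if str(value).lower() in ("false", "0", "no"):
            return False
        raise DataError(f"config key {key!r}: expected a boolean, got {value!r}")
    try:
        return typ(value)
    except (TypeError, ValueError) as exc:
        raise DataError(
            f"config key {key!r}: expected {typ.__name__}, got {value!r}"
        ) from exc


def parse_config(
    config_file: Optional[str | Path] = None,
    overrides: Optional[dict[str, Any]] = None,
) -> tuple[PredictionConfig, dict[str, Any]]:
    """Resolve a prediction configuration from an optional YAML file plus
    CLI overrides (overrides win).  Unknown keys are errors, with a
    suggestion for near-misses.  With no file and no overrides this yields
    the ``default`` preset."""
    merged: dict[str, Any] = {}
    sources: list[dict[str, Any]] = []
    if config_file is not None:
        raw = yaml.safe_load(Path(config_file).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise DataError(f"{config_file}: expected a key/value mapping")
        sources.append(raw)
    if overrides:
        sources.append({k: v for k, v in overrides.items() if v is not None})
    for src in sources:
        for key, value in src.items():
            if key not in _CONFIG_KEYS:
                hint = difflib.get_close_matches(key, _CONFIG_KEYS, n=1)
                suffix = f"; did you mean {hint[0]!r}?" if hint else ""
                raise DataError(f"unknown config key {key!r}{suffix}")
            merged[key] = _coerce(key, value)

    base = preset(merged.pop("preset", "default"))
    params = base.params
    if "energy" in merged:
        params = load_parameters(merged.pop("energy"))
    sc = base.seed
    ic = base.interaction
    sc_kwargs: dict[str, Any] = {}
    ic_kwargs: dict[str, Any] = {}
    for key, value in merged.items():
        if key == "seedRequired":
            sc_kwargs["seed_required"] = value
        elif key in ("seedBP", "allowGU", "seedMaxE", "seedMaxEhybrid", "seedMinPu"):
            sc_kwargs[key] = value
        else:
            ic_kwargs[key] = value
    from dataclasses import replace

    try:
        cfg = PredictionConfig(
            seed=replace(sc, **sc_kwargs),
            interaction=replace(ic, **ic_kwargs),
            params=params,
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    resolved = {
        "preset": "default" if config_file is None and not overrides else "custom",
        "energy": params.name,
        "seedRequired": cfg.seed.seed_required,
        "seedBP": cfg.seed.seedBP,
        "allowGU": cfg.seed.allowGU,
        "seedMaxE": cfg.seed.seedMaxE,
        "seedMaxEhybrid": cfg.seed.seedMaxEhybrid,
        "seedMinPu": cfg.seed.seedMinPu,
        "intLenMax": cfg.interaction.intLenMax,
        "intMaxE": cfg.interaction.intMaxE,
        "intMinPu": cfg.interaction.intMinPu,
        "maxLoop": cfg.interaction.maxLoop,
        "temperature": cfg.params.temperature,
    }
    return cfg, resolved


# ---------------------------------------------------------------------------
# provenance

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def provenance_header(
    resolved: dict[str, Any], inputs: dict[str, Path] | None = None
) -> list[str]:
    """Machine-readable '#'-prefixed provenance lines for output files:
    tool version, resolved configuration, input checksums.  Coordinates in
    all outputs are 1-based inclusive."""
    from . import __version__

    lines = [f"# seedscan {__version__}", "# coordinates: 1-based inclusive"]
    for key in sorted(resolved):
        lines.append(f"# config {key}={resolved[key]}")
    for name, path in sorted((inputs or {}).items()):
        lines.append(f"# input {name}={Path(path).name} sha256:{file_checksum(path)}")
    return lines
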