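"""Flat-text run configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Named parameters for every stage, serializable to a flat ``key = value`` file.

    Every parameter has a default; unknown keys in a config file are
    rejected rather than ignored, so typos surface immediately.
    """

    # randomness
    seed: int = 0

    # PICS confidence thresholds ("over 80%" / "over 10%", strict by default)
    test_confidence_min: float = 0.8
    control_confidence_min: float = 0.1
    strict_thresholds: bool = True
    # peptide handling
    deduplicate_peptides: bool = True
    ambiguous_p_side: str = "p_prime_only"  # or "drop"
    # simulator digestion / MS observability
    min_peptide_length: int = 6
    max_peptide_length: int = 30
    missed_cleavages: int = 0
    digest_mode: str = "combined"  # or "pooled" (separate digests, pooled)
    # CSP / Kd fitting
    csp_alpha: float = 0.2
    reporter_k: float = 1.0
    # alignment scoring (needle-style defaults)
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False
    # structure comparison
    prune_factor: float = 2.0
    min_pairs: int = 3
    selection: str = "*:-999999-999999:all"

    def __post_init__(self) -> None:
        if self.ambiguous_p_side not in ("p_prime_only", "drop"):
            raise ValueError(f"ambiguous_p_side must be 'p_prime_only' or 'drop', got {self.ambiguous_p_side!r}")
        if self.digest_mode not in ("combined", "pooled"):
            raise ValueError(f"digest_mode must be 'combined' or 'pooled', got {self.digest_mode!r}")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse(value, known[key])
        return cls(**kwargs)  # type: ignore[arg-type]

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)


def _parse(value: str, typ: str | type) -> object:
    name = typ if isinstance(typ, str) else typ.__name__
    if name == "bool":
        low = value.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    if name == "int":
        return int(value)
    if name == "float":
        return float(value)
    return value
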