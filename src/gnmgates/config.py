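"""Analysis configuration with flat key=value file round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .exceptions import InputError, ValidationError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Fixed constants of the method plus run options.

    Defaults follow the method's canonical settings: a 7 Å contact
    cutoff, unit spring constant and thermal energy, the largest-
    eigenvalue mode, the contact-restricted D statistic, ten top
    residues and a 1% perturbation.
    """

    cutoff: float = 7.0
    gamma: float = 1.0
    kT: float = 1.0
    mode_selection: str = "max"
    variant: str = "contact_sum"
    top_k: int = 10
    delta: float = 0.01
    chains: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.gamma <= 0 or self.kT <= 0:
            raise ValidationError("gamma and kT must be positive")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.variant not in ("contact_sum", "all_pairs"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if isinstance(self.chains, (list, set)):
            self.chains = tuple(sorted(self.chains))

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "chains":
                value = "" if value is None else ",".join(value)
            lines.append(f"{f.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AnalysisConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"config line {lineno} is not key = value: {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise InputError(f"unknown config key {key!r}")
            if key == "chains":
                kwargs[key] = tuple(v for v in value.split(",") if v) or None
            elif key in ("top_k", "seed"):
                kwargs[key] = int(value)
            elif key in ("mode_selection", "variant"):
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        return cls.from_text(path.read_text())
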