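"""Flat key/value run configuration: a diffable experiment record.

The file format is one `key = value` pair per line (# comments allowed).
Defaults reproduce the shipped settings: lambda = 2, w = 0.1, SMOTE K = 5,
decision threshold 0.5, and the per-localization (gamma, cost) optima.
Per-localization SVM overrides use dotted keys, e.g. `svm.nucleus.gamma`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from mirnaloc.model import SvmConfig, DEFAULT_SVM_CONFIGS


def _default_svm() -> dict[str, SvmConfig]:
    return dict(DEFAULT_SVM_CONFIGS)


@dataclass
class RunConfig:
    """Encoder, SMOTE, SVM, CV and seed settings for a pipeline run."""

    lam: int = 2
    w: float = 0.1
    property_table: str = ""  # empty = embedded asset
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    smote_skip_threshold: float = 1.5
    threshold: float = 0.5
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    svm: dict[str, SvmConfig] = field(default_factory=_default_svm)

    _SCALARS = (
        "lam", "w", "property_table", "smote_k", "smote_target_ratio",
        "smote_skip_threshold", "threshold", "folds", "repeats", "seed",
    )

    def to_text(self) -> str:
        lines = []
        for name in self._SCALARS:
            lines.append(f"{name} = {getattr(self, name)}")
        for loc in sorted(self.svm):
            cfg = self.svm[loc]
            lines.append(f"svm.{loc}.gamma = {cfg.gamma}")
            lines.append(f"svm.{loc}.cost = {cfg.cost}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        scalars: dict[str, str] = {}
        svm_raw: dict[str, dict[str, float]] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("svm."):
                _, loc, param = key.split(".", 2)
                if param not in ("gamma", "cost"):
                    raise ValueError(f"line {lineno}: unknown SVM parameter {param!r}")
                svm_raw.setdefault(loc, {})[param] = float(value)
            else:
                scalars[key] = value

        cfg = cls()
        for key, value in scalars.items():
            if key not in cls._SCALARS:
                raise ValueError(f"unknown configuration key {key!r}")
            current = getattr(cfg, key)
            caster = type(current)
            setattr(cfg, key, caster(value) if caster is not str else value)
        for loc, params in svm_raw.items():
            base = cfg.svm.get(loc, SvmConfig())
            cfg.svm[loc] = SvmConfig(
                gamma=params.get("gamma", base.gamma),
                cost=params.get("cost", base.cost),
            )
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())
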