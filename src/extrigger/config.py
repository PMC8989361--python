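"""Run configuration: every tunable of the decision pipeline in one place.

A flat key = value config file can override any field; the effective settings
are echoed into every machine-readable output header so a run can always be
reproduced from its artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Defaults follow the published case-study choices.

    ``w1`` is either the string "calibrated" (ln(20) / first observed
    abundance, i.e. 95% satisfaction at the pre-decline population) or an
    explicit float; ``w2`` is the captive-population preference discount;
    ``px`` the ex situ establishment probability.
    """

    w1: float | str = "calibrated"
    w2: float = 2.0 / 3.0
    px: float = 0.75
    horizon_percentile: float = 0.99
    horizon_cap: int | None = None  # None -> max(5 x observed span, 100)
    n_rate_nodes: int = 201
    slope_dist: str = "normal"       # normal | t
    belief_variant: str = "conjugate"  # conjugate | as_printed
    clamp: str = "floor"             # floor | raw
    reference: str = "last_observed"  # last_observed | fitted
    fit_window: int = 3
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("w2", "px", "horizon_percentile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if isinstance(self.w1, str) and self.w1 != "calibrated":
            raise ValueError("w1 must be 'calibrated' or a positive number")
        if not isinstance(self.w1, str) and self.w1 <= 0:
            raise ValueError("w1 must be positive")
        if self.fit_window < 3:
            raise ValueError("fit_window must be >= 3")
        if self.n_rate_nodes < 1:
            raise ValueError("n_rate_nodes must be >= 1")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def header_lines(self, prefix: str = "# ") -> list[str]:
        """Effective settings as comment lines for output headers."""
        return [f"{prefix}{k} = {v}" for k, v in self.as_dict().items()]


_FIELD_TYPES = {
    "w1": "w1", "w2": float, "px": float, "horizon_percentile": float,
    "horizon_cap": "opt_int", "n_rate_nodes": int, "slope_dist": str,
    "belief_variant": str, "clamp": str, "reference": str,
    "fit_window": int, "seed": int, "verbosity": int,
}


def _coerce(name: str, raw: str):
    kind = _FIELD_TYPES[name]
    raw = raw.strip()
    if kind == "w1":
        return raw if raw == "calibrated" else float(raw)
    if kind == "opt_int":
        return None if raw.lower() in ("none", "") else int(raw)
    return kind(raw)


def load_config(path, base: RunConfig | None = None) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments, blank lines ok)."""
    base = base or RunConfig()
    overrides = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in stripped.split("=", 1))
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            try:
                overrides[key] = _coerce(key, raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key}: {exc}")
    return base.with_overrides(**overrides)
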