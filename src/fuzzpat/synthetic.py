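"""Synthetic mixed-mode benchmark data with known cluster structure.

Twenty attributes: A1, A2 binary symbols {T, F}; A3-A5 ternary symbols
{X, Y, Z}; A6-A20 continuous in [0, 1].  Three intrinsic attribute
groups are wired in through three driver attributes:

* A1 drives A7 (low half when A1 = T) and A8-A12 (low half when A1 = F);
* A13 drives A2, A3 (thresholds at 0.2 / 0.4), A14-A17 and A18-A20
  (three aligned / rotated sub-ranges with breakpoints 0.3 / 0.6);
* A6 — itself range-coupled to A1 and A13 — drives A4 (breakpoints
  0.3 / 0.6) and A5 (breakpoints 0.2 / 0.4).

Five classes are imposed by constraining (A1, A13) per class; the
default imposition (T with A13 in [0, .2), [.2, .4), [.4, .7); F with
A13 in [.7, 1] or [0, .5)) keeps the five classes distinguishable by
(A1, A6, A13) while every conditional rule above stays intact.  Class
sizes default to (500, 300, 300, 400, 300) — 1800 tuples — and 25%
noise is injected by replacing the attribute values (not the labels) of
a sample-without-replacement subset of tuples with uniform draws over
each attribute's whole domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CONTINUOUS, MixedModeTable

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "validate_structure"]

DEFAULT_CLASS_SIZES = (500, 300, 300, 400, 300)
# per class: (A1 value, A13 range)
DEFAULT_CLASS_SCHEME = (
    ("T", (0.0, 0.2)),
    ("T", (0.2, 0.4)),
    ("T", (0.4, 0.7)),
    ("F", (0.7, 1.0)),
    ("F", (0.0, 0.5)),
)
ATTRIBUTE_NAMES = tuple(f"A{i}" for i in range(1, 21))
KINDS = {
    **{f"A{i}": CATEGORICAL for i in range(1, 6)},
    **{f"A{i}": CONTINUOUS for i in range(6, 21)},
}


@dataclass
class GeneratorConfig:
    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    noise_fraction: float = 0.25
    seed: int = 0
    class_scheme: tuple = DEFAULT_CLASS_SCHEME

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must lie in [0, 1)")
        if len(self.class_sizes) != len(self.class_scheme):
            raise ValueError("one scheme entry per class required")


@dataclass
class SyntheticDataset:
    table: MixedModeTable
    noise_mask: np.ndarray
    config: GeneratorConfig


def _ternary(values: np.ndarray, lo: float, hi: float, labels: tuple[str, str, str]) -> np.ndarray:
    out = np.where(values < lo, labels[0], np.where(values < hi, labels[1], labels[2]))
    return out.astype(object)


def generate(config: GeneratorConfig | None = None, **kwargs) -> SyntheticDataset:
    """Generate the benchmark table; fully reproducible from the seed."""
    if config is None:
        config = GeneratorConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    n = int(sum(config.class_sizes))

    labels = np.concatenate(
        [np.full(sz, f"C{c + 1}", dtype=object) for c, sz in enumerate(config.class_sizes)]
    )
    a1 = np.concatenate(
        [np.full(sz, scheme[0], dtype=object)
         for sz, scheme in zip(config.class_sizes, config.class_scheme)]
    )
    a13 = np.concatenate(
        [rng.uniform(lo, hi, size=sz)
         for sz, (_, (lo, hi)) in zip(config.class_sizes, config.class_scheme)]
    )

    u = rng.uniform(0.0, 1.0, size=n)
    t_low = (a1 == "T") & (a13 < 0.5)
    t_high = (a1 == "T") & (a13 >= 0.5)
    a6 = np.where(t_low, 0.7 * u, np.where(t_high, 0.3 + 0.5 * u, u))

    a2 = np.where(a13 < 0.2, "T", "F").astype(object)
    a3 = _ternary(a13, 0.2, 0.4, ("X", "Y", "Z"))
    a4 = _ternary(a6, 0.3, 0.6, ("X", "Y", "Z"))
    a5 = _ternary(a6, 0.2, 0.4, ("Y", "Z", "X"))

    def half(flag: np.ndarray) -> np.ndarray:
        # low half [0, 0.5] when flag, upper half (0.5, 1] otherwise
        draw = rng.uniform(0.0, 0.5, size=n)
        return np.where(flag, draw, 1.0 - draw)

    a7 = half(a1 == "T")
    a8_12 = [half(a1 == "F") for _ in range(5)]

    def banded(shift: int) -> np.ndarray:
        # three A13-bands mapped to sub-ranges, optionally rotated
        band = np.digitize(a13, [0.3, 0.6])  # 0,1,2
        band = (band + shift) % 3
        widths = np.array([0.3, 0.3, 0.4])
        starts = np.array([0.0, 0.3, 0.6])
        draw = rng.uniform(0.0, 1.0, size=n)
        return starts[band] + widths[band] * draw

    a14_17 = [banded(0) for _ in range(4)]
    a18_20 = [banded(1) for _ in range(3)]

    data = {
        "A1": a1, "A2": a2, "A3": a3, "A4": a4, "A5": a5,
        "A6": a6, "A7": a7,
        **{f"A{8 + i}": col for i, col in enumerate(a8_12)},
        "A13": a13,
        **{f"A{14 + i}": col for i, col in enumerate(a14_17)},
        **{f"A{18 + i}": col for i, col in enumerate(a18_20)},
    }
    df = pd.DataFrame(data, columns=list(ATTRIBUTE_NAMES))

    n_noise = int(np.floor(config.noise_fraction * n))
    noise_idx = rng.choice(n, size=n_noise, replace=False)
    noise_mask = np.zeros(n, dtype=bool)
    noise_mask[noise_idx] = True
    for name in ("A1", "A2"):
        df.loc[noise_mask, name] = rng.choice(["T", "F"], size=n_noise)
    for name in ("A3", "A4", "A5"):
        df.loc[noise_mask, name] = rng.choice(["X", "Y", "Z"], size=n_noise)
    for i in range(6, 21):
        df.loc[noise_mask, f"A{i}"] = rng.uniform(0.0, 1.0, size=n_noise)

    table = MixedModeTable(df, dict(KINDS), pd.Series(labels, name="class"))
    return SyntheticDataset(table, noise_mask, config)


@dataclass
class StructureReport:
    class_counts: dict[str, int]
    n_violations: int
    violations: list[tuple[int, str]]
    empirical_noise_fraction: float


def _range_ok(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (v >= lo) & (v <= hi)


def validate_structure(
    table: MixedModeTable, noise_mask: np.ndarray | None = None
) -> StructureReport:
    """Check every conditional generation rule tuple by tuple.

    With a noise mask, violations are counted among non-noise tuples
    only (a correct generation run reports zero); without one, the
    violating fraction doubles as a crude noise estimate.  Each
    (tuple, attribute-rule) failure counts as one violation.
    """
    df = table.values
    n = table.n_samples
    checks: list[tuple[str, np.ndarray]] = []
    a13 = df["A13"].to_numpy(dtype=float)
    a6 = df["A6"].to_numpy(dtype=float)
    a1 = df["A1"].to_numpy()
    checks.append(("A2", (df["A2"].to_numpy() == np.where(a13 < 0.2, "T", "F"))))
    checks.append(("A3", df["A3"].to_numpy() == _ternary(a13, 0.2, 0.4, ("X", "Y", "Z"))))
    checks.append(("A4", df["A4"].to_numpy() == _ternary(a6, 0.3, 0.6, ("X", "Y", "Z"))))
    checks.append(("A5", df["A5"].to_numpy() == _ternary(a6, 0.2, 0.4, ("Y", "Z", "X"))))
    a6_ok = np.where(
        (a1 == "T") & (a13 < 0.5), _range_ok(a6, 0.0, 0.7),
        np.where((a1 == "T"), _range_ok(a6, 0.3, 0.8), _range_ok(a6, 0.0, 1.0)),
    )
    checks.append(("A6", a6_ok.astype(bool)))
    a7 = df["A7"].to_numpy(dtype=float)
    checks.append(("A7", np.where(a1 == "T", _range_ok(a7, 0, 0.5), _range_ok(a7, 0.5, 1.0))))
    for i in range(8, 13):
        v = df[f"A{i}"].to_numpy(dtype=float)
        checks.append((f"A{i}", np.where(a1 == "F", _range_ok(v, 0, 0.5), _range_ok(v, 0.5, 1.0))))
    band = np.digitize(a13, [0.3, 0.6])
    bounds = np.array([[0.0, 0.3], [0.3, 0.6], [0.6, 1.0]])
    for i in range(14, 18):
        v = df[f"A{i}"].to_numpy(dtype=float)
        checks.append((f"A{i}", _range_ok(v, bounds[band, 0], bounds[band, 1])))
    rot = (band + 1) % 3
    for i in range(18, 21):
        v = df[f"A{i}"].to_numpy(dtype=float)
        checks.append((f"A{i}", _range_ok(v, bounds[rot, 0], bounds[rot, 1])))

    consider = ~noise_mask if noise_mask is not None else np.ones(n, dtype=bool)
    violations = [
        (int(i), name) for name, ok in checks for i in np.flatnonzero(~ok & consider)
    ]
    any_bad = np.zeros(n, dtype=bool)
    for _, ok in checks:
        any_bad |= ~ok
    if table.class_labels is not None:
        counts = table.class_labels.value_counts().to_dict()
    else:
        counts = {}
    noise_frac = (
        float(noise_mask.mean()) if noise_mask is not None else float(any_bad.mean())
    )
    return StructureReport(
        {str(k): int(v) for k, v in counts.items()},
        len(violations),
        violations,
        noise_frac,
    )
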