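"""Per-prey parameter bundles for *Bdellovibrio bacteriovorus* predation.

All quantitative constants used by the simulator, the synthetic-data
generators and the summary stage live here as typed, validated bundles:
the OD600→cells/mL conversion for each prey species, the predator
inoculum, the progeny-count distribution, and the single-cell event
timings (replisome, segrosome and divisome appearance times) with their
95% confidence intervals.

Every ``a ± h`` entry is interpreted as a normal-theory 95% confidence
interval of the mean with the stated sample size, so the underlying
per-cell standard deviation is recovered as ``h·√n/1.96``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SPECIES",
    "SummaryStat",
    "PreyParams",
    "load_prey_params",
    "sd_from_ci95",
    "Z95",
]

#: z-quantile used throughout for 95% intervals (normality assumed, not a t-quantile).
Z95 = 1.96

#: Known prey species keys.
SPECIES = ("P_mirabilis", "S_enterica", "S_flexneri", "E_coli")


def sd_from_ci95(half_width: float, n: int) -> float:
    """Back-derive a sample standard deviation from a 95% CI half-width.

    Inverts the normal-theory interval of the mean, ``half = 1.96·sd/√n``.

    Parameters
    ----------
    half_width
        CI half-width, in the native units of the measurement. Must be ≥ 0.
    n
        Sample size used to form the interval. Must be ≥ 1.

    Returns
    -------
    float
        ``half_width · √n / 1.96`` in the same units as ``half_width``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    return half_width * math.sqrt(n) / Z95


class SummaryStat(BaseModel):
    """Mean with 95% CI half-width, sample size, and back-derived SD."""

    mean: float
    ci95_half: float = Field(ge=0)
    n: int = Field(gt=0)

    @property
    def sd(self) -> float:
        """Per-observation standard deviation implied by the CI of the mean."""
        return sd_from_ci95(self.ci95_half, self.n)

    @model_validator(mode="after")
    def _finite(self) -> "SummaryStat":
        if not (math.isfinite(self.mean) and math.isfinite(self.ci95_half)):
            raise ValueError("mean and ci95_half must be finite")
        return self

    def __repr__(self) -> str:  # compact: "46 ± 4 (n=100)"
        return f"SummaryStat({self.mean:g} ± {self.ci95_half:g}, n={self.n})"


class PreyParams(BaseModel):
    """Complete parameter bundle for one prey species.

    Fields that the source measurements do not provide for a species
    (e.g. no timing data for *E. coli*) are ``None`` / empty, and all
    downstream operations tolerate their absence.
    """

    species: str
    cells_per_ml_at_od1: Optional[float] = Field(default=None, gt=0)
    culture_volume_ml: float = Field(default=0.28, gt=0)
    predator_inoculum: float = Field(default=2.1e7, gt=0)
    progeny_pmf: dict[int, float]
    progeny_mean: float = Field(gt=0)
    lifecycle: Optional[SummaryStat] = None
    cycle_step_min: Optional[int] = Field(default=None, gt=0)
    event_timings: dict[str, SummaryStat] = Field(default_factory=dict)
    progeny_length: Optional[SummaryStat] = None

    @property
    def ftsZ_duration(self) -> Optional[SummaryStat]:
        """Duration the FtsZ ring stays visible (``d_ftsZ`` timing), if measured."""
        return self.event_timings.get("d_ftsZ")

    @property
    def initial_prey(self) -> Optional[float]:
        """Default starting prey population: culture volume × cells/mL at OD 1.0."""
        if self.cells_per_ml_at_od1 is None:
            return None
        return self.culture_volume_ml * self.cells_per_ml_at_od1

    @model_validator(mode="after")
    def _check_invariants(self) -> "PreyParams":
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; known: {', '.join(SPECIES)}"
            )
        total = sum(self.progeny_pmf.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"progeny_pmf probabilities sum to {total}, not 1")
        if any(k < 1 or k != int(k) for k in self.progeny_pmf):
            raise ValueError("progeny_pmf support must be positive integers")
        if any(p < 0 for p in self.progeny_pmf.values()):
            raise ValueError("progeny_pmf probabilities must be non-negative")
        implied = sum(k * p for k, p in self.progeny_pmf.items())
        if abs(implied - self.progeny_mean) > 1e-9:
            raise ValueError(
                f"progeny_mean {self.progeny_mean} != pmf mean {implied}"
            )
        if self.lifecycle is not None and self.cycle_step_min is not None:
            rounded = round(self.lifecycle.mean / 10) * 10
            if self.cycle_step_min != rounded:
                raise ValueError(
                    f"cycle_step_min {self.cycle_step_min} != lifecycle mean "
                    f"{self.lifecycle.mean} rounded to nearest 10 ({rounded})"
                )
        return self

    # -- JSON round trip -------------------------------------------------

    def to_json(self, path: Optional[str | Path] = None, **kwargs) -> str:
        """Serialize to JSON (UTF-8); optionally write to ``path``."""
        text = json.dumps(self.model_dump(mode="json"), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PreyParams":
        """Load a bundle from a JSON string or file path."""
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text(encoding="utf-8") if p is not None else str(source)
        return cls.model_validate(json.loads(text))


def _stat(mean: float, half: float, n: int = 100) -> SummaryStat:
    return SummaryStat(mean=mean, ci95_half=half, n=n)


def _builtin_bundles() -> dict[str, dict]:
    """Built-in default bundles, exactly the printed study values.

    Progeny pmfs: only the supports and modes are printed ("two to five,
    usually 3 or 4" for S. enterica; "four to eight, usually 5 to 7" for
    S. flexneri); the default frequencies below realise those shapes with
    means 2.0 / 3.5 / 6.0, the values under which the simulator reproduces
    the printed complete-lysis times. The E. coli pmf ({3, 4} equally) is
    likewise an assumption anchored only to "usually 3 or 4".
    """
    return {
        "P_mirabilis": dict(
            species="P_mirabilis",
            cells_per_ml_at_od1=1.5e9,
            progeny_pmf={2: 1.0},
            progeny_mean=2.0,
            lifecycle=_stat(252, 7),
            cycle_step_min=250,
            event_timings={
                "t_dnaN1": _stat(46, 4),
                "t_parB2": _stat(69, 4),
                "d_oric_migration": _stat(19, 2),
                "t_dnaN2": _stat(79, 6),
                "d_replication": _stat(144, 7),
                "t_ftsZ1": _stat(165, 4),
                "d_ftsZ": _stat(49, 3),
                "t_release": _stat(252, 7),
            },
            progeny_length=_stat(1.25, 0.03),
        ),
        "S_enterica": dict(
            species="S_enterica",
            cells_per_ml_at_od1=9.5e8,
            progeny_pmf={2: 0.1, 3: 0.4, 4: 0.4, 5: 0.1},
            progeny_mean=3.5,
            lifecycle=_stat(288, 7),
            cycle_step_min=290,
            event_timings={
                "t_dnaN1": _stat(46, 5),
                "t_parB2": _stat(65, 5),
                "d_oric_migration": _stat(18, 2),
                "t_dnaN2": _stat(119, 7),
                "t_parB3": _stat(138, 8),
                "t_dnaN3": _stat(163, 9),
                "t_parB4": _stat(182, 10),
                "t_ftsZ1": _stat(217, 5),
                "t_ftsZ2": _stat(225, 6),
                "t_ftsZ3": _stat(244, 6),
                "d_ftsZ": _stat(52, 6),
                "t_release": _stat(288, 7),
            },
            progeny_length=_stat(1.16, 0.03),
        ),
        "S_flexneri": dict(
            species="S_flexneri",
            cells_per_ml_at_od1=3e8,
            progeny_pmf={4: 0.1, 5: 0.25, 6: 0.3, 7: 0.25, 8: 0.1},
            progeny_mean=6.0,
            lifecycle=_stat(379, 11),
            cycle_step_min=380,
            event_timings={
                "t_dnaN1": _stat(44, 5),
                "t_parB2": _stat(76, 6),
                "d_oric_migration": _stat(17, 2),
                "t_dnaN2": _stat(128, 7),
                "t_parB3": _stat(144, 7),
                "t_dnaN3": _stat(191, 9),
                "t_parB4": _stat(211, 8),
                "t_ftsZ1": _stat(310, 9),
                "t_release": _stat(379, 11),
            },
            progeny_length=_stat(1.35, 0.03),
        ),
        # E. coli: only progeny-length and qualitative progeny counts are
        # measured; no OD conversion or timing entries.
        "E_coli": dict(
            species="E_coli",
            progeny_pmf={3: 0.5, 4: 0.5},
            progeny_mean=3.5,
            progeny_length=_stat(1.11, 0.04),
        ),
    }


def load_prey_params(species: str, overrides: Optional[dict] = None) -> PreyParams:
    """Load the validated parameter bundle for a prey species.

    Parameters
    ----------
    species
        One of ``P_mirabilis``, ``S_enterica``, ``S_flexneri``, ``E_coli``.
    overrides
        Optional mapping of field name → value, merged over the built-in
        defaults before validation. An unknown ``species`` with a complete
        override bundle is rejected only if the species key itself is
        unknown.

    Raises
    ------
    ValueError
        Unknown species, or an override bundle violating any invariant.
    """
    bundles = _builtin_bundles()
    if species not in bundles:
        raise ValueError(
            f"unknown species {species!r}; known: {', '.join(bundles)}"
        )
    cfg = bundles[species]
    if overrides:
        cfg = {**cfg, **overrides}
    return PreyParams.model_validate(cfg)
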