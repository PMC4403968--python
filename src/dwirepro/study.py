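"""Multi-scanner study design and metric-level measurement simulation.

The volunteer arm of a multi-centre reproducibility study is modelled at
the level of per-session ROI means: for each diffusion metric and region,

    value(scanner i, volunteer j, session k)
        = grand_mean + scanner_offset_i + v_j + eps_ijk

with the scanner entering as an additive fixed effect, the volunteer as a
zero-mean Gaussian random effect of SD ``volunteer_sd`` and a session
residual of SD ``residual_sd``. This is exactly the generative model the
downstream mixed-effect analysis assumes, so the generator doubles as the
ground truth for variance-component recovery tests.

``replica_study_design`` reproduces the layout of the reference study:
eight scanners (four 1.5 T, four 3 T) across five centres, nine
volunteers, between four and eight volunteers per scanner, thirteen
repeat sessions, 65 imaging sessions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScannerProfile",
    "StudyDesign",
    "replica_study_design",
    "generate_multicentre_study",
    "METRICS",
]

#: Canonical diffusion metrics, in report order.
METRICS = ("ADC", "D", "f", "MD", "FA")

#: Default per-metric/region true means on the reporting scale
#: (ADC/D/MD in 1e-3 mm^2 s^-1; f and FA dimensionless), typical of
#: healthy adult grey and white matter.
DEFAULT_GRAND_MEANS = {
    "ADC": {"GM": 0.83, "WM": 0.70},
    "D": {"GM": 0.75, "WM": 0.65},
    "f": {"GM": 0.10, "WM": 0.08},
    "MD": {"GM": 0.85, "WM": 0.70},
    "FA": {"GM": 0.17, "WM": 0.42},
}

#: Default effect-size SDs per metric (same reporting scale). Chosen to be
#: of the order of the between-scanner / between-volunteer / session
#: spreads reported for overall grey and white matter in multi-centre
#: diffusion studies.
DEFAULT_SCANNER_OFFSET_SD = {"ADC": 0.020, "D": 0.022, "f": 0.020,
                             "MD": 0.015, "FA": 0.006}
DEFAULT_VOLUNTEER_SD = {"ADC": 0.020, "D": 0.015, "f": 0.003,
                        "MD": 0.012, "FA": 0.012}
DEFAULT_RESIDUAL_SD = {"ADC": 0.015, "D": 0.012, "f": 0.008,
                       "MD": 0.015, "FA": 0.011}


class DesignError(ValueError):
    """Invalid study design."""


@dataclass(frozen=True)
class ScannerProfile:
    """One scanner: field strength, additive fixed effects, noise scale.

    metric_offsets maps metric name -> additive fixed effect in the
    metric's own units; noise_sigma is the Rician noise scale used by the
    image-level simulator (unused by the metric-level generator).
    """

    scanner_id: str
    field_strength: float
    metric_offsets: dict = field(default_factory=dict)
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.field_strength not in (1.5, 3.0, 3):
            raise DesignError(
                f"field_strength must be 1.5 or 3, got {self.field_strength}"
            )
        if self.noise_sigma < 0:
            raise DesignError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Scanner/volunteer/session layout plus simulation effect sizes.

    volunteers_per_scanner : scanner_id -> tuple of volunteer ids
    repeat_sessions : (scanner_id, volunteer_id) -> session count (>= 1);
        pairs not listed default to a single session.
    grand_mean : metric -> region -> true mean
    volunteer_sd, residual_sd : metric -> SD (>= 0)
    """

    scanners: tuple
    volunteers_per_scanner: dict
    repeat_sessions: dict
    grand_mean: dict
    volunteer_sd: dict
    residual_sd: dict

    def __post_init__(self):
        if not self.scanners:
            raise DesignError("design has no scanners")
        ids = [s.scanner_id for s in self.scanners]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate scanner ids")
        for sid in self.volunteers_per_scanner:
            if sid not in ids:
                raise DesignError(f"unknown scanner id {sid!r} in layout")
        if not any(self.volunteers_per_scanner.values()):
            raise DesignError("design has no volunteers")
        for sd_map in (self.volunteer_sd, self.residual_sd):
            for m, sd in sd_map.items():
                if sd < 0:
                    raise DesignError(f"negative SD for metric {m!r}")

    @property
    def metrics(self) -> tuple:
        return tuple(self.grand_mean)

    @property
    def regions(self) -> tuple:
        first = next(iter(self.grand_mean.values()))
        return tuple(first)

    @property
    def volunteer_ids(self) -> tuple:
        vols = sorted({v for vs in self.volunteers_per_scanner.values() for v in vs})
        return tuple(vols)

    def session_count(self, scanner_id: str, volunteer_id: str) -> int:
        return int(self.repeat_sessions.get((scanner_id, volunteer_id), 1))

    @property
    def n_sessions(self) -> int:
        return sum(
            self.session_count(sid, v)
            for sid, vols in self.volunteers_per_scanner.items()
            for v in vols
        )

    def profile(self, scanner_id: str) -> ScannerProfile:
        for s in self.scanners:
            if s.scanner_id == scanner_id:
                return s
        raise KeyError(scanner_id)


def replica_study_design(
    seed: int = 0,
    scanner_offset_sd: dict | None = None,
    volunteer_sd: dict | None = None,
    residual_sd: dict | None = None,
    grand_mean: dict | None = None,
) -> StudyDesign:
    """The eight-scanner, nine-volunteer, 65-session reference layout.

    Scanners A, B, D, G are 1.5 T; C, E, F, H are 3 T. One volunteer on
    each of C, D, E and two volunteers on each of A, B, F, G, H attend a
    repeat session. Scanner fixed effects are sampled once per metric with
    SD ``scanner_offset_sd`` from a generator derived from ``seed`` (the
    design is then fully deterministic).
    """
    offset_sd = dict(DEFAULT_SCANNER_OFFSET_SD, **(scanner_offset_sd or {}))
    gm = grand_mean or DEFAULT_GRAND_MEANS
    metrics = tuple(gm)

    field_strengths = {"A": 1.5, "B": 1.5, "C": 3.0, "D": 1.5,
                       "E": 3.0, "F": 3.0, "G": 1.5, "H": 3.0}
    # volunteers per scanner: counts 8,7,6,6,6,7,6,6 (sum 52) + 13 repeats = 65
    vols = [f"V{i}" for i in range(1, 10)]
    layout = {
        "A": tuple(vols[0:8]),
        "B": tuple(vols[0:7]),
        "C": tuple(vols[0:6]),
        "D": tuple(vols[1:7]),
        "E": tuple(vols[2:8]),
        "F": tuple(vols[0:7]),
        "G": tuple(vols[3:9]),
        "H": tuple(vols[0:6]),
    }
    repeats = {}
    for sid, doubled in [("A", 2), ("B", 2), ("C", 1), ("D", 1),
                         ("E", 1), ("F", 2), ("G", 2), ("H", 2)]:
        for v in layout[sid][:doubled]:
            repeats[(sid, v)] = 2

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CA33E]))
    scanners = []
    for sid in "ABCDEFGH":
        offsets = {m: float(rng.normal(0.0, offset_sd[m])) for m in metrics}
        scanners.append(
            ScannerProfile(scanner_id=sid, field_strength=field_strengths[sid],
                           metric_offsets=offsets)
        )

    return StudyDesign(
        scanners=tuple(scanners),
        volunteers_per_scanner=layout,
        repeat_sessions=repeats,
        grand_mean=gm,
        volunteer_sd=dict(DEFAULT_VOLUNTEER_SD, **(volunteer_sd or {})),
        residual_sd=dict(DEFAULT_RESIDUAL_SD, **(residual_sd or {})),
    )


def generate_multicentre_study(
    design: StudyDesign, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Simulate the long-format measurement table for a study design.

    Returns ``(table, truth)``. The table has one row per
    (scanner, volunteer, session, region, metric) with columns
    ``scanner, volunteer, session, region, metric, value``; the row count
    per metric/region equals the designed session count. ``truth`` records
    the grand means, scanner offsets, sampled volunteer effects and the
    design SDs for recovery tests.

    All randomness flows from ``seed`` through spawned child generators,
    so identical seeds give identical tables.
    """
    ss = np.random.SeedSequence(int(seed))
    child_vol, child_res = ss.spawn(2)
    rng_vol = np.random.default_rng(child_vol)
    rng_res = np.random.default_rng(child_res)

    metrics = design.metrics
    regions = design.regions
    vol_ids = design.volunteer_ids

    # volunteer random effects, drawn per metric/region/volunteer
    vol_effects = {
        (m, r, v): float(rng_vol.normal(0.0, design.volunteer_sd.get(m, 0.0)))
        for m in metrics
        for r in regions
        for v in vol_ids
    }

    rows = []
    for sid in sorted(design.volunteers_per_scanner):
        prof = design.profile(sid)
        for v in design.volunteers_per_scanner[sid]:
            for k in range(design.session_count(sid, v)):
                session = f"{sid}-{v}-s{k + 1}"
                for r in regions:
                    for m in metrics:
                        eps = rng_res.normal(0.0, design.residual_sd.get(m, 0.0))
                        value = (
                            design.grand_mean[m][r]
                            + prof.metric_offsets.get(m, 0.0)
                            + vol_effects[(m, r, v)]
                            + eps
                        )
                        rows.append((sid, v, session, r, m, value))

    table = pd.DataFrame(
        rows, columns=["scanner", "volunteer", "session", "region",
                       "metric", "value"]
    )
    truth = {
        "grand_mean": design.grand_mean,
        "scanner_offsets": {
            s.scanner_id: dict(s.metric_offsets) for s in design.scanners
        },
        "volunteer_effects": {
            f"{m}/{r}/{v}": e for (m, r, v), e in vol_effects.items()
        },
        "volunteer_sd": dict(design.volunteer_sd),
        "residual_sd": dict(design.residual_sd),
    }
    return table, truth
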