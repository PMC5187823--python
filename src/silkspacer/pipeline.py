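"""End-to-end orchestration: simulate → assign → 3₁ → fibril → shifts → report.

A :class:`RunConfig` (usually read from YAML) fully determines a run;
all randomness flows from one root seed that is split per stage, so a
repeated run with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assign import assign_ensemble, region_fractions
from .exceptions import ConfigError
from .fibril import RegionSpec, bending_angles, region_rmsd_report
from .pgii import composition_stats, detect_pgii_frame, estimate_occurrence
from .shifts import classify_shift, load_reference_table
from .structures import ConformerEnsemble, read_ensemble_pdb, write_ensemble_pdb
from .synthetic import (
    MASP1_FIRST_RESNUM,
    MASP1_SEQUENCE,
    SPACER_RANGE,
    FibrilSpec,
    build_backbone,
    build_fibril,
    make_library,
    parse_replica_ladder,
    sample_ensemble,
    uniform_dihedrals,
)

logger = logging.getLogger("silkspacer")

#: Default spacer-state occupancies: the reported AP spacer composition
#: (3₁₀ split evenly by hand, 3₁ as pgii, remainder renormalised).
DEFAULT_OCCUPANCIES = {
    "310R": 0.0205,
    "310L": 0.0205,
    "pgii": 0.001,
    "turn": 0.306,
    "coil": 0.325,
    "beta": 0.264,
    "alpha": 0.007,
}


def _normalised(occ: dict[str, float]) -> dict[str, float]:
    total = sum(occ.values())
    if total <= 0:
        raise ConfigError("state occupancies sum to zero")
    return {k: v / total for k, v in occ.items()}


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    sequence: str = MASP1_SEQUENCE
    first_resnum: int = MASP1_FIRST_RESNUM
    fibril: dict = field(default_factory=lambda: {
        "planes": 1, "strands": 1, "between_plane": "parallel",
        "strand_spacing": 4.8, "plane_spacing": 5.3,
    })
    states: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCIES)
    )
    sigma: float = 10.0
    region: tuple[int, int] = SPACER_RANGE
    regions: dict = field(default_factory=lambda: {
        "polya1": (71, 81), "spacer": SPACER_RANGE, "polya2": (108, 121),
    })
    n_frames: int = 200
    mode: str = "segment"
    n_samples: int = 400
    n_bootstrap: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.region = tuple(self.region)
        if self.region[0] > self.region[1]:
            raise ConfigError(f"empty spacer region {self.region}")
        lo = self.first_resnum
        hi = self.first_resnum + len(self.sequence) - 1
        if not (lo <= self.region[0] <= self.region[1] <= hi):
            raise ConfigError(
                f"region {self.region} outside strand numbering {lo}-{hi}"
            )
        if self.n_frames < 1 or self.n_samples < 1 or self.n_bootstrap < 1:
            raise ConfigError("n_frames, n_samples, n_bootstrap must be >= 1")
        self.states = _normalised(self.states)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def build_template(config: RunConfig):
    """The starting structure: a single extended strand or a mini-fibril."""
    fib = config.fibril
    spec = FibrilSpec(
        n_planes=int(fib.get("planes", 1)),
        n_strands_per_plane=int(fib.get("strands", 1)),
        between_plane_orientation=fib.get("between_plane", "parallel"),
        inter_strand_spacing=float(fib.get("strand_spacing", 4.8)),
        inter_plane_spacing=float(fib.get("plane_spacing", 5.3)),
    )
    if spec.n_planes == 1 and spec.n_strands_per_plane == 1:
        n = len(config.sequence)
        return build_backbone(
            config.sequence, uniform_dihedrals(n, -135.0, 135.0),
            first_resnum=config.first_resnum,
        )
    return build_fibril(
        spec, config.sequence, first_resnum=config.first_resnum
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the JSON-serialisable report."""
    rng = np.random.default_rng(config.seed)
    stage_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]

    logger.info("stage build: %d-residue strand", len(config.sequence))
    template = build_template(config)
    logger.info("stage simulate: %d frames, %d chains",
                config.n_frames, template.n_chains)
    library = make_library(config.states, sigma=config.sigma)
    ensemble = sample_ensemble(
        template, library, region=config.region, n_frames=config.n_frames,
        seed=stage_seeds[0], mode=config.mode,
    )

    logger.info("stage assign")
    assignments = assign_ensemble(ensemble)
    fractions = region_fractions(assignments, ensemble, config.region)

    logger.info("stage pgii")
    occurrence = estimate_occurrence(
        ensemble, n_samples=min(config.n_samples, config.n_frames),
        n_bootstrap=config.n_bootstrap, seed=stage_seeds[1],
    )
    composition = composition_stats(
        ensemble, assignments=assignments,
        n_bootstrap=config.n_bootstrap, seed=stage_seeds[2],
    )

    logger.info("stage fibril")
    regions = RegionSpec(
        tuple(config.regions["polya1"]),
        tuple(config.regions["spacer"]),
        tuple(config.regions["polya2"]),
    )
    fibril_block: dict = {}
    if config.n_frames >= 2:
        bending = bending_angles(ensemble, regions)
        rmsd = region_rmsd_report(ensemble, regions)
        fibril_block = {
            "bending_deg": {k: list(v) for k, v in bending.summary().items()},
            "rmsd_A": {k: list(v) for k, v in rmsd.items()},
        }

    logger.info("stage shifts")
    table = load_reference_table()
    shift_block = []
    for rec in table:
        if rec.conformation != "observed":
            continue
        try:
            cls = classify_shift(rec.residue, rec.atom, rec.midpoint, table)
        except Exception:
            continue
        shift_block.append({
            "residue": rec.residue, "atom": rec.atom, "ppm": rec.midpoint,
            "top_class": cls.top, "ambiguous": cls.ambiguous,
            "secondary_shift": cls.secondary_shift,
            "ranking": cls.ranking,
        })

    report = {
        "schema_version": 1,
        "software_version": __version__,
        "config": _config_echo(config),
        "stage_seeds": stage_seeds,
        "replica_ladders": {
            "AP": len(parse_replica_ladder(system="AP")),
            "AA": len(parse_replica_ladder(system="AA")),
        },
        "ss_fractions_percent": fractions.percent,
        "ss_handedness_percent": fractions.by_handedness,
        "pgii_occurrence": {
            "fraction_frames": occurrence.fraction_frames,
            "segments_per_frame": occurrence.segments_per_frame,
            "ci95": [occurrence.ci_low, occurrence.ci_high],
            "n_sampled": occurrence.n_sampled,
        },
        "composition": {
            "pgii": {
                p: {aa: list(v) for aa, v in d.items()}
                for p, d in composition.pgii.items()
            },
            "g310": composition.g310,
            "g310_hbond_A": [composition.hbond_mean, composition.hbond_sd],
        },
        "fibril": fibril_block,
        "shift_classification": shift_block,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ensemble_pdb(ensemble, str(out / "ensemble.pdb"))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("report written to %s", out / "report.json")
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["region"] = list(config.region)
    return echo


def read_ensemble(path: str) -> ConformerEnsemble:
    """Read a multi-model PDB ensemble (missing amide H synthesised)."""
    return read_ensemble_pdb(path)
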