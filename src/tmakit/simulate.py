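"""Simulated study fixtures.

Real input to the toolkit is a scanner export: a directory of per-core
JPEGs plus slide metadata. No public TMA image repository ships such
exports, so the simulator builds a complete, deterministic stand-in study:
array layouts with donor-block replicates and optional gaps and marker
cores, a populated study store with slidemaps and score templates, one
synthetic core image per used position named under the export convention,
and (optionally) simulated scores from one or more scorers.

Everything derives from a single integer seed plus an injected clock, so
two runs with the same parameters produce byte-identical trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tmakit.clock import FixedClock
from tmakit.imaging.export import export_core_image
from tmakit.imaging.synthetic import SyntheticCoreSpec, generate_synthetic_core
from tmakit.scoring import ScoreRecord, get_builtin_system
from tmakit.slidemap import parse_layout_table, RecipientBlock
from tmakit.store import StudyStore

logger = logging.getLogger(__name__)

__all__ = ["SimulationSpec", "SimulationResult", "simulate_study"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a simulated scoring study.

    One slide is produced per (marker, slide index); all slides of a study
    share the same array layout, as they would when serial sections of one
    recipient block are stained for different markers.
    """

    study_id: str = "SIM"
    markers: tuple[str, ...] = ("ER", "PR")
    n_slides_per_marker: int = 1
    n_cols: int = 3
    n_rows: int = 3
    gap_fraction: float = 0.0
    n_marker_cores: int = 0
    scorers: tuple[str, ...] = ("path1",)
    system_name: str = "intensity-0-3"
    score_fraction: float = 1.0
    core_size_px: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gap_fraction <= 1):
            raise ValueError("gap_fraction must be in [0, 1]")
        if not (0 <= self.score_fraction <= 1):
            raise ValueError("score_fraction must be in [0, 1]")
        if self.n_marker_cores + 1 > self.n_cols * self.n_rows:
            raise ValueError("too many marker cores for the grid")


@dataclass
class SimulationResult:
    store: StudyStore
    image_dir: Path
    slide_ids: list[str] = field(default_factory=list)
    n_images: int = 0
    n_scores: int = 0


def _make_layout(spec: SimulationSpec, rng: np.random.Generator) -> list[list[str]]:
    cells = []
    n = spec.n_cols * spec.n_rows
    donor_counter = 0
    flat: list[str] = []
    for i in range(n):
        flat.append("")
    # marker cores first (top-left corner positions), then tissue/gaps
    order = list(range(n))
    for i in range(spec.n_marker_cores):
        flat[order[i]] = "MARKER"
    for i in range(spec.n_marker_cores, n):
        if rng.uniform() < spec.gap_fraction:
            flat[i] = ""
        else:
            donor_counter += 1
            flat[i] = f"DB{donor_counter:03d}"
    for r in range(spec.n_rows):
        cells.append(flat[r * spec.n_cols : (r + 1) * spec.n_cols])
    return cells


def simulate_study(
    spec: SimulationSpec,
    store_root: str | Path,
    image_dir: str | Path,
    clock: FixedClock | None = None,
) -> SimulationResult:
    """Build a complete simulated study under ``store_root``/``image_dir``.

    Creates the study and marker collections, one slidemap per slide (all
    markers share the layout drawn once from the seed), grants every
    scorer every marker, opens slide documents (generating templates),
    writes one synthetic core JPEG per used position, and records
    simulated scores for ``score_fraction`` of the tissue cores.
    """
    rng = np.random.default_rng(spec.seed)
    clock = clock or FixedClock()
    store = StudyStore(store_root)
    result = SimulationResult(store=store, image_dir=Path(image_dir))

    store.create_study(spec.study_id)
    layout = _make_layout(spec, rng)
    system = get_builtin_system(spec.system_name)

    for marker in spec.markers:
        store.add_marker(spec.study_id, marker)
        for scorer in spec.scorers:
            store.grant(scorer, spec.study_id, marker)
        for slide_idx in range(1, spec.n_slides_per_marker + 1):
            slide_id = f"{spec.study_id}-{marker}-{slide_idx}"
            block = RecipientBlock(
                block_id=f"{spec.study_id}-B{slide_idx}",
                n_cols=spec.n_cols,
                n_rows=spec.n_rows,
                slice_number=slide_idx,
            )
            slidemap = parse_layout_table(layout, block, slide_id, marker)
            store.add_slidemap(spec.study_id, marker, slidemap)
            result.slide_ids.append(slide_id)

            # one synthetic core image per used position
            for p in slidemap.positions:
                if not p.used:
                    continue
                true_grade = int(rng.integers(0, 4))
                core_spec = SyntheticCoreSpec(
                    size_px=spec.core_size_px,
                    stain_intensity=true_grade,
                    stained_fraction=float(rng.uniform(0.2, 0.8)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                image = generate_synthetic_core(
                    core_spec, slide_id=slide_id, x=p.x, y=p.y
                )
                export_core_image(image, result.image_dir)
                result.n_images += 1

            for scorer in spec.scorers:
                store.open_slide(
                    spec.study_id, marker, scorer, slide_id, system
                )
                for p in slidemap.tissue_positions:
                    if rng.uniform() >= spec.score_fraction:
                        continue
                    record = ScoreRecord(
                        slide_id=slide_id, x=p.x, y=p.y,
                        scorer=scorer, marker=marker,
                        values=_draw_values(system.name, rng),
                        timestamp=clock.now(),
                    )
                    store.record_score(spec.study_id, marker, record)
                    result.n_scores += 1
    logger.info(
        "simulated study %s: %d slides, %d images, %d scores",
        spec.study_id, len(result.slide_ids), result.n_images, result.n_scores,
    )
    return result


def _draw_values(system_name: str, rng: np.random.Generator) -> dict:
    if system_name == "intensity-0-3":
        return {"intensity": int(rng.integers(0, 4))}
    if system_name == "allred":
        intensity = int(rng.integers(0, 4))
        proportion = 0 if intensity == 0 else int(rng.integers(1, 6))
        return {
            "intensity": intensity,
            "proportion": proportion,
            "total": intensity + proportion,
        }
    if system_name == "percentage":
        return {"percent_staining": float(np.round(rng.uniform(0, 100), 1))}
    if system_name == "her2-ihc":
        return {"her2_status": str(rng.choice(["0", "1+", "2+", "3+"]))}
    if system_name == "binary":
        return {"result": str(rng.choice(["positive", "negative"]))}
    raise ValueError(f"no value generator for system {system_name!r}")
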