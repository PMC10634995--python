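"""Parameterized synthetic solenoid backbones with known ground truth.

Every pipeline stage is testable without structure downloads: a helical coil
(the "LRR") of stated period, radius and rise is sandwiched between
random-walk flanks, optionally interrupted by a straight out-and-back
hairpin excursion, and perturbed with isotropic Gaussian coordinate noise.
The generator records where the coil, the repeat boundaries and the hairpin
truly are, so boundary- and anomaly-recovery can be measured exactly.

Defaults mimic a canonical plant-NLR LRR: 24 residues per turn, ~8 Å coil
radius, ~5 Å rise per turn, and Cα-scale 3.8 Å steps in the flanks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import BackboneCurve, ResidueLabel


@dataclass(frozen=True)
class SolenoidSpec:
    """Parameters of one synthetic solenoid backbone."""

    period: int = 24  # residues per coil turn
    turns: float = 10.0
    coil_radius: float = 8.0  # Å
    rise_per_turn: float = 5.0  # Å
    axis: str = "straight"  # "straight" or "arc"
    axis_curvature: float = 0.0  # 1/Å, used when axis == "arc"
    noise_sd: float = 0.0  # Å, isotropic, added last
    flank_n: int = 0  # residues of random-walk flank before the coil
    flank_c: int = 0  # residues after the coil
    hairpin: Optional[tuple[int, int]] = None  # (position within coil, length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 3:
            raise ValueError("period must be at least 3 residues")
        if self.turns <= 0:
            raise ValueError("turns must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.coil_radius <= 0 or self.rise_per_turn <= 0:
            raise ValueError("coil_radius and rise_per_turn must be positive")
        if self.axis not in ("straight", "arc"):
            raise ValueError("axis must be 'straight' or 'arc'")
        if self.axis == "arc" and self.axis_curvature <= 0:
            raise ValueError("arc axis requires positive axis_curvature")
        if self.flank_n < 0 or self.flank_c < 0:
            raise ValueError("flank lengths must be non-negative")
        if self.hairpin is not None:
            pos, length = self.hairpin
            n_coil = int(round(self.turns * self.period)) + 1
            if not (0 < pos < n_coil - 1):
                raise ValueError("hairpin position must lie inside the coil")
            if length < 2:
                raise ValueError("hairpin length must be at least 2")


@dataclass(frozen=True)
class SolenoidTruth:
    """Ground truth of a generated fixture (0-based indices into the curve)."""

    lrr_start: int
    lrr_end: int  # inclusive
    repeat_starts: tuple[int, ...]
    hairpin_interval: Optional[tuple[int, int]]  # inclusive, None if no hairpin
    n_residues: int

    def to_dict(self) -> dict:
        return asdict(self)


STEP = 3.8  # Å, Cα-Cα distance enforced on flanks and hairpins
MIN_CLEARANCE = 3.0  # Å, self-avoidance radius for flank random walks


def _coil_points(spec: SolenoidSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Helix points plus the axis tangent directions at the two coil ends."""
    n = int(round(spec.turns * spec.period)) + 1
    t = np.arange(n, dtype=float)
    phase = 2.0 * np.pi * t / spec.period
    s = spec.rise_per_turn * t / spec.period  # arc length along the axis
    if spec.axis == "straight":
        axis_pts = np.column_stack([np.zeros(n), np.zeros(n), s])
        e1 = np.tile([1.0, 0.0, 0.0], (n, 1))
        e2 = np.tile([0.0, 1.0, 0.0], (n, 1))
        axis_start = axis_end = np.array([0.0, 0.0, 1.0])
    else:
        big_r = 1.0 / spec.axis_curvature
        ang = s / big_r
        axis_pts = np.column_stack(
            [big_r * np.sin(ang), np.zeros(n), big_r * (1.0 - np.cos(ang))]
        )
        # normal-plane frame of the arc: in-plane radial (away from the
        # center of curvature at (0, 0, big_r)) + out-of-plane y
        e1 = np.column_stack([np.sin(ang), np.zeros(n), -np.cos(ang)])
        e2 = np.tile([0.0, 1.0, 0.0], (n, 1))
        axis_start = np.array([np.cos(ang[0]), 0.0, np.sin(ang[0])])
        axis_end = np.array([np.cos(ang[-1]), 0.0, np.sin(ang[-1])])
    pts = axis_pts + spec.coil_radius * (
        np.cos(phase)[:, None] * e1 + np.sin(phase)[:, None] * e2
    )
    return pts, axis_start, axis_end


TURN_MIN, TURN_MAX = np.deg2rad(2.0), np.deg2rad(15.0)  # per-step turning angles


def _random_walk(
    start: np.ndarray,
    first_direction: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Persistent self-avoiding 3.8 Å-step random walk starting one step
    from ``start``.

    Each step turns by a small random angle (2-15 degrees, random azimuth)
    from the previous direction, emulating the semi-extended linker and
    terminal segments that flank solenoid domains at these lengths (tens of
    residues); steps that come within MIN_CLEARANCE of earlier walk points
    are rejected and redrawn.
    """
    points: list[np.ndarray] = []
    current = start
    direction = first_direction / np.linalg.norm(first_direction)
    for step in range(n_steps):
        candidate = current + STEP * direction
        for _ in range(200):
            if step == 0:
                new_dir = direction
            else:
                theta = rng.uniform(TURN_MIN, TURN_MAX)
                perp = rng.normal(size=3)
                perp -= np.dot(perp, direction) * direction
                perp /= np.linalg.norm(perp)
                new_dir = direction * np.cos(theta) + perp * np.sin(theta)
            candidate = current + STEP * new_dir
            if all(np.linalg.norm(candidate - p) >= MIN_CLEARANCE for p in points):
                direction = new_dir
                break
        # on exhausted retries the last candidate is accepted
        points.append(candidate)
        current = candidate
    return np.array(points) if points else np.zeros((0, 3))


def make_solenoid(spec: SolenoidSpec) -> tuple[BackboneCurve, SolenoidTruth]:
    """Generate a synthetic backbone and its ground-truth record.

    The coil is sampled one residue per step on the helix; flanks are
    self-avoiding random walks with 3.8 Å steps; the optional hairpin is a
    straight out-and-back excursion perpendicular to the local coil tangent
    (the return leg is offset ~1 Å along the coil so the curve stays
    non-degenerate); isotropic Gaussian noise is added last.
    """
    rng = np.random.default_rng(spec.seed)
    coil, axis_start, axis_end = _coil_points(spec)

    if spec.hairpin is not None:
        pos, length = spec.hairpin
        tangent = coil[min(pos + 1, len(coil) - 1)] - coil[pos - 1]
        tangent /= np.linalg.norm(tangent)
        radial = rng.normal(size=3)
        radial -= np.dot(radial, tangent) * tangent
        radial /= np.linalg.norm(radial)
        n_out = (length + 1) // 2
        n_back = length - n_out
        out_pts = [coil[pos] + STEP * (i + 1) * radial for i in range(n_out)]
        lateral = 1.0 * tangent
        back_pts = [
            coil[pos] + STEP * (n_back - j) * radial + lateral for j in range(n_back)
        ]
        excursion = np.array(out_pts + back_pts)
        coil = np.vstack([coil[: pos + 1], excursion, coil[pos + 1 :]])
        hairpin_interval: Optional[tuple[int, int]] = (pos + 1, pos + length)
    else:
        pos, length = -1, 0
        hairpin_interval = None

    # flanks exit along the solenoid axis, like the linkers that connect an
    # LRR to its neighboring domains
    flank_parts: list[np.ndarray] = []
    if spec.flank_n:
        walk = _random_walk(coil[0], -axis_start, spec.flank_n, rng)
        flank_parts.append(walk[::-1])
    flank_parts.append(coil)
    if spec.flank_c:
        flank_parts.append(_random_walk(coil[-1], axis_end, spec.flank_c, rng))
    points = np.vstack(flank_parts)

    if spec.noise_sd > 0:
        points = points + rng.normal(scale=spec.noise_sd, size=points.shape)

    lrr_start = spec.flank_n
    lrr_end = spec.flank_n + len(coil) - 1
    base_repeats = [
        lrr_start + k * spec.period for k in range(int(spec.turns) + 1)
        if k * spec.period < len(coil)
    ]
    if hairpin_interval is not None:
        shifted = []
        for r in base_repeats:
            coil_idx = r - lrr_start
            shifted.append(r + length if coil_idx > pos else r)
        base_repeats = shifted
        hairpin_interval = (
            hairpin_interval[0] + lrr_start,
            hairpin_interval[1] + lrr_start,
        )
    labels = tuple(
        ResidueLabel("A", i + 1, "") for i in range(len(points))
    )
    curve = BackboneCurve(
        points=points,
        residue_labels=labels,
        source_id=f"synthetic:period={spec.period},turns={spec.turns},seed={spec.seed}",
    )
    truth = SolenoidTruth(
        lrr_start=lrr_start,
        lrr_end=lrr_end,
        repeat_starts=tuple(base_repeats),
        hairpin_interval=hairpin_interval,
        n_residues=len(points),
    )
    return curve, truth


def write_pdb_fixture(curve: BackboneCurve, path: str | Path) -> None:
    """Write a minimal CA-only PDB file readable by read_backbone (1e-3 Å)."""
    path = Path(path)
    lines = []
    for i, (pt, lab) in enumerate(zip(curve.points, curve.residue_labels)):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA {lab.chain[:1] or 'A'}{lab.number:4d}"
            f"{lab.icode or ' ':1s}   "
            f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_truth(truth: SolenoidTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
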