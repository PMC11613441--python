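"""Extended-XYZ trajectory reading/writing and small table outputs.

The extended-XYZ dialect used here carries the periodic box in the
comment line as ``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"`` together with a
``Properties=`` declaration and optional per-frame scalars
(``energy=...``), which is what most visualization tools expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Frame:
    """One trajectory frame: positions (N, 3), diagonal box, extras."""

    positions: np.ndarray
    box: tuple[float, float, float]
    velocities: np.ndarray | None = None
    species: list[str] | None = None
    scalars: dict = field(default_factory=dict)


class XYZParseError(ValueError):
    pass


def write_xyz(path, frames) -> None:
    """Write frames as extended XYZ (positions in nm)."""
    with open(path, "w") as fh:
        for fr in frames:
            n = len(fr.positions)
            lat = (f'Lattice="{fr.box[0]:.10g} 0 0 0 {fr.box[1]:.10g} 0 0 0 '
                   f'{fr.box[2]:.10g}"')
            props = "Properties=species:S:1:pos:R:3"
            if fr.velocities is not None:
                props += ":vel:R:3"
            extras = " ".join(f"{k}={v:.10g}" for k, v in fr.scalars.items())
            fh.write(f"{n}\n{lat} {props}{(' ' + extras) if extras else ''}\n")
            sp = fr.species or ["X"] * n
            for i in range(n):
                x, y, z = fr.positions[i]
                line = f"{sp[i]} {x:.9f} {y:.9f} {z:.9f}"
                if fr.velocities is not None:
                    vx, vy, vz = fr.velocities[i]
                    line += f" {vx:.9f} {vy:.9f} {vz:.9f}"
                fh.write(line + "\n")


def _parse_comment(comment: str):
    box = None
    scalars = {}
    has_vel = False
    i = 0
    # tokenize key=value pairs, honoring quoted values
    while i < len(comment):
        eq = comment.find("=", i)
        if eq < 0:
            break
        key = comment[comment.rfind(" ", 0, eq) + 1:eq]
        j = eq + 1
        if j < len(comment) and comment[j] == '"':
            end = comment.find('"', j + 1)
            val = comment[j + 1:end]
            i = end + 1
        else:
            end = comment.find(" ", j)
            end = len(comment) if end < 0 else end
            val = comment[j:end]
            i = end
        if key.lower() == "lattice":
            cells = [float(t) for t in val.split()]
            if len(cells) != 9:
                raise XYZParseError("Lattice needs 9 numbers")
            box = (cells[0], cells[4], cells[8])
        elif key.lower() == "properties":
            has_vel = ":vel:" in val.lower()
        else:
            try:
                scalars[key] = float(val)
            except ValueError:
                scalars[key] = val
    return box, scalars, has_vel


def read_xyz(path) -> list[Frame]:
    """Read an extended-XYZ trajectory; raises with a line number on
    malformed input."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise XYZParseError(
                f"frame {frame_no} at line {i + 1}: body truncated "
                f"(need {n} atom lines)"
            )
        box, scalars, has_vel = _parse_comment(lines[i + 1].strip())
        if box is None:
            raise XYZParseError(f"frame {frame_no}: missing Lattice entry")
        pos = np.empty((n, 3))
        vel = np.empty((n, 3)) if has_vel else None
        species = []
        for k in range(n):
            toks = lines[i + 2 + k].split()
            want = 7 if has_vel else 4
            if len(toks) < want:
                raise XYZParseError(
                    f"frame {frame_no}, line {i + 3 + k}: expected "
                    f"{want} columns, got {len(toks)}"
                )
            species.append(toks[0])
            pos[k] = [float(t) for t in toks[1:4]]
            if has_vel:
                vel[k] = [float(t) for t in toks[4:7]]
        frames.append(Frame(pos, box, vel, species, scalars))
        i += 2 + n
        frame_no += 1
    return frames
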