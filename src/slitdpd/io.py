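"""Trajectory and configuration serialization.

Trajectories use a self-describing extended-XYZ dialect: each frame is a
bead count line, a key=value comment line (step, geometry, instantaneous
kT), and one line per bead with columns

    species x y z vx vy vz chain_id frozen

Floats are written with 17 significant digits so a read/write round trip
is bit-exact.  Run configurations use flat INI sections ([species],
[interactions], [geometry], [run]); the parsed config is echoed into
output headers for provenance.
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path
from typing import Iterator, TextIO

import numpy as np

from .builder import Configuration
from .model import (
    SPECIES,
    BoxGeometry,
    ChainSpec,
    InteractionTable,
    SystemParams,
)

__all__ = [
    "write_frame",
    "write_trajectory",
    "read_trajectory",
    "read_frames",
    "parse_config",
    "write_config",
]

_COLUMNS = "species:S:1:pos:R:3:vel:R:3:chain_id:I:1:frozen:I:1"


class TrajectoryFormatError(ValueError):
    """Raised on malformed trajectory files, with the offending line number."""


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_frame(config: Configuration, sink: TextIO) -> None:
    """Append one configuration as an extended-XYZ block."""
    g = config.geometry
    header = (
        f'step={config.time} kind={g.kind} Lx={_fmt(g.Lx)} Ly={_fmt(g.Ly)} '
        f'Lz={_fmt(g.Lz)} x_c={_fmt(g.x_c)} a_wall={_fmt(g.a_wall)} '
        f'Properties={_COLUMNS}'
    )
    if "kT_inst" in config.meta:
        header += f' kT_inst={_fmt(config.meta["kT_inst"])}'
    sink.write(f"{config.n_beads}\n{header}\n")
    p, v = config.positions, config.velocities
    for i in range(config.n_beads):
        sink.write(
            f"{config.species[i]} {_fmt(p[i, 0])} {_fmt(p[i, 1])} {_fmt(p[i, 2])} "
            f"{_fmt(v[i, 0])} {_fmt(v[i, 1])} {_fmt(v[i, 2])} "
            f"{config.chain_id[i]} {int(config.frozen[i])}\n"
        )


def write_trajectory(frames, path: str | Path) -> None:
    """Write an iterable of configurations to one trajectory file."""
    with open(path, "w") as fh:
        for cfg in frames:
            write_frame(cfg, fh)


def _parse_header(line: str, lineno: int) -> dict:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            raise TrajectoryFormatError(
                f"line {lineno}: malformed header token {tok!r}"
            )
        k, v = tok.split("=", 1)
        out[k] = v
    if "Properties" not in out:
        raise TrajectoryFormatError(
            f"line {lineno}: unsupported dialect (missing Properties header)"
        )
    if out["Properties"] != _COLUMNS:
        raise TrajectoryFormatError(
            f"line {lineno}: unsupported dialect: columns {out['Properties']!r}, "
            f"expected {_COLUMNS!r} (chain_id/frozen columns are required)"
        )
    return out


def read_frames(source: str | Path | TextIO) -> Iterator[Configuration]:
    """Lazily iterate configurations from an extended-XYZ trajectory.

    Earlier frames remain usable if the file ends mid-frame; the truncated
    frame raises with its line number.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        lineno = 0
        while True:
            count_line = fh.readline()
            if not count_line:
                return
            lineno += 1
            if not count_line.strip():
                continue
            try:
                n = int(count_line)
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"line {lineno}: expected bead count, got {count_line.strip()!r}"
                ) from exc
            header_line = fh.readline()
            lineno += 1
            if not header_line:
                raise TrajectoryFormatError(f"line {lineno}: truncated frame header")
            hdr = _parse_header(header_line.strip(), lineno)
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            species = np.empty(n, dtype="<U1")
            chain_id = np.empty(n, dtype=np.int64)
            frozen = np.empty(n, dtype=bool)
            for i in range(n):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise TrajectoryFormatError(
                        f"line {lineno}: truncated frame (bead {i + 1}/{n} missing)"
                    )
                parts = line.split()
                if len(parts) != 9:
                    raise TrajectoryFormatError(
                        f"line {lineno}: expected 9 columns, got {len(parts)}"
                    )
                if parts[0] not in SPECIES:
                    raise TrajectoryFormatError(
                        f"line {lineno}: unknown species {parts[0]!r}"
                    )
                species[i] = parts[0]
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                vel[i] = [float(parts[4]), float(parts[5]), float(parts[6])]
                chain_id[i] = int(parts[7])
                frozen[i] = bool(int(parts[8]))
            geom = BoxGeometry(
                kind=hdr.get("kind", "bulk"),
                Lx=float(hdr["Lx"]),
                Ly=float(hdr["Ly"]),
                Lz=float(hdr["Lz"]),
                x_c=float(hdr.get("x_c", 1.2)),
                a_wall=float(hdr.get("a_wall", 25.0)),
            )
            meta = {}
            if "kT_inst" in hdr:
                meta["kT_inst"] = float(hdr["kT_inst"])
            yield Configuration(
                positions=pos, velocities=vel, species=species,
                chain_id=chain_id, frozen=frozen, geometry=geom,
                time=int(hdr.get("step", 0)), meta=meta,
            )
    finally:
        if own:
            fh.close()


def read_trajectory(source: str | Path | TextIO) -> list[Configuration]:
    """Read all frames of a trajectory file into memory."""
    return list(read_frames(source))


# ---------------------------------------------------------------------------
# run-configuration files (INI)
# ---------------------------------------------------------------------------

def parse_config(path: str | Path) -> dict:
    """Parse an INI run configuration into model objects.

    Sections: [species] (blocks, K, r0), [interactions] (a_XY pairs, gamma,
    sigma), [geometry] (kind, D or L, Ly, Lz, x_c, a_wall), [run] (rho,
    n_chains or c, steps, pre_equil_steps, sample_period, seed).
    Unspecified keys fall back to the package defaults.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)

    blocks_raw = cp.get("species", "blocks", fallback="A5B5")
    blocks = _parse_blocks(blocks_raw)
    chain = ChainSpec(
        blocks=blocks,
        K=cp.getfloat("species", "K", fallback=4.0),
        r0=cp.getfloat("species", "r0", fallback=0.0),
    )

    table = InteractionTable.default(
        a_BW=cp.getfloat("interactions", "a_BW", fallback=25.0)
    )
    if cp.has_section("interactions"):
        for key, val in cp.items("interactions"):
            if key.startswith("a_") and len(key) == 4:
                table.set_pair(key[2].upper(), key[3].upper(), float(val))
            elif key == "gamma":
                table.gamma = float(val)
            elif key == "sigma":
                table.sigma = float(val)
    table.check_fdt()

    kind = cp.get("geometry", "kind", fallback="bulk")
    Ly = cp.getfloat("geometry", "Ly", fallback=cp.getfloat("geometry", "L", fallback=25.0))
    Lz = cp.getfloat("geometry", "Lz", fallback=Ly)
    if kind == "slit":
        geom = BoxGeometry(
            kind="slit",
            Lx=cp.getfloat("geometry", "D"),
            Ly=Ly,
            Lz=Lz,
            x_c=cp.getfloat("geometry", "x_c", fallback=1.2),
            a_wall=cp.getfloat("geometry", "a_wall", fallback=25.0),
        )
    else:
        geom = BoxGeometry(
            kind="bulk",
            Lx=cp.getfloat("geometry", "Lx", fallback=Ly),
            Ly=Ly,
            Lz=Lz,
        )

    rho = cp.getfloat("run", "rho", fallback=3.0)
    if cp.has_option("run", "n_chains"):
        n_chains = cp.getint("run", "n_chains")
    elif cp.has_option("run", "c"):
        from .model import chains_for_concentration

        n_chains = chains_for_concentration(
            cp.getfloat("run", "c"), chain.n, rho, geom.volume
        )
    else:
        n_chains = 0
    params = SystemParams(
        rho=rho,
        n_chains=n_chains,
        steps=cp.getint("run", "steps", fallback=0),
        pre_equil_steps=cp.getint("run", "pre_equil_steps", fallback=0),
        sample_period=cp.getint("run", "sample_period", fallback=10_000),
        seed=cp.getint("run", "seed", fallback=0),
    )
    return {"chain": chain, "table": table, "geom": geom, "params": params}


def _parse_blocks(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a block string like 'A5B5' into ((A,5),(B,5))."""
    blocks = []
    sp, num = None, ""
    for ch in text.strip():
        if ch.isalpha():
            if sp is not None:
                blocks.append((sp, int(num) if num else 1))
            sp, num = ch.upper(), ""
        elif ch.isdigit():
            num += ch
        else:
            raise ValueError(f"bad block architecture string {text!r}")
    if sp is not None:
        blocks.append((sp, int(num) if num else 1))
    if not blocks:
        raise ValueError(f"bad block architecture string {text!r}")
    return tuple(blocks)


def _config_parser(bundle: dict) -> configparser.ConfigParser:
    chain: ChainSpec = bundle["chain"]
    table: InteractionTable = bundle["table"]
    geom: BoxGeometry = bundle["geom"]
    params: SystemParams = bundle["params"]
    cp = configparser.ConfigParser()
    cp["species"] = {
        "blocks": "".join(f"{s}{n}" for s, n in chain.blocks),
        "K": repr(chain.K),
        "r0": repr(chain.r0),
    }
    inter = {f"a_{k}": repr(v) for k, v in sorted(table.a.items())}
    inter["gamma"] = repr(table.gamma)
    inter["sigma"] = repr(table.sigma)
    cp["interactions"] = inter
    if geom.kind == "slit":
        cp["geometry"] = {
            "kind": "slit", "D": repr(geom.Lx), "Ly": repr(geom.Ly),
            "Lz": repr(geom.Lz), "x_c": repr(geom.x_c), "a_wall": repr(geom.a_wall),
        }
    else:
        cp["geometry"] = {
            "kind": "bulk", "Lx": repr(geom.Lx), "Ly": repr(geom.Ly),
            "Lz": repr(geom.Lz),
        }
    cp["run"] = {
        "rho": repr(params.rho),
        "n_chains": str(params.n_chains),
        "steps": str(params.steps),
        "pre_equil_steps": str(params.pre_equil_steps),
        "sample_period": str(params.sample_period),
        "seed": str(params.seed),
    }
    return cp


def write_config(bundle: dict, path: str | Path) -> None:
    """Write the model objects back to an INI file (inverse of parse_config)."""
    with open(path, "w") as fh:
        _config_parser(bundle).write(fh)


def config_to_string(bundle: dict) -> str:
    """Render a config bundle as INI text (for output-header provenance)."""
    buf = _io.StringIO()
    _config_parser(bundle).write(buf)
    return buf.getvalue()
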