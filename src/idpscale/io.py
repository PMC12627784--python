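"""Plain-text file formats for decays, photon streams, curves and trajectories.

All formats are columnar text (whitespace-separated) with JSON sidecars for
metadata, so every artefact remains diffable and portable:

* decay histograms: ``time_ns  counts`` + sidecar (period_ns, polarization);
* photon streams: ``time_s  channel``; FCS arrivals: single ``time_s`` column;
* correlation curves: ``lag_ms  G``;
* scaling tables: TSV with variant_id, N_res, R_E_nm, sigma_nm;
* trajectories: XYZ frames + JSON manifest (box, frame interval, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from idpscale.burst_fret import Burst, PhotonStream
from idpscale.decay_flim import DecayHistogram
from idpscale.fcs_diffusion import CorrelationCurve
from idpscale.cg_sim.engine import TrajectoryFrames

__all__ = [
    "write_decay", "read_decay",
    "write_photon_stream", "read_photon_stream",
    "write_arrival_times", "read_arrival_times",
    "write_correlation", "read_correlation",
    "write_scaling_table", "read_scaling_table",
    "write_burst_table",
    "write_xyz", "read_xyz",
    "read_fasta_sequence", "read_pdb_ca_coords",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_decay(path, decay: DecayHistogram) -> None:
    path = Path(path)
    np.savetxt(path, np.column_stack([decay.bin_times, decay.counts]),
               header="time_ns counts", fmt="%.12g")
    _sidecar(path).write_text(json.dumps(
        {"period_ns": decay.period_ns, "polarization": decay.polarization}
    ))


def read_decay(path) -> DecayHistogram:
    path = Path(path)
    data = np.loadtxt(path)
    meta = json.loads(_sidecar(path).read_text())
    return DecayHistogram(bin_times=data[:, 0], counts=data[:, 1],
                          period_ns=float(meta["period_ns"]),
                          polarization=meta.get("polarization", "combined"))


def write_photon_stream(path, stream: PhotonStream) -> None:
    np.savetxt(Path(path), np.column_stack([stream.times, stream.channels]),
               header="time_s channel", fmt=("%.9f", "%d"))


def read_photon_stream(path) -> PhotonStream:
    data = np.loadtxt(Path(path), ndmin=2)
    return PhotonStream(times=data[:, 0], channels=data[:, 1].astype(np.int8))


def write_arrival_times(path, times_s: np.ndarray) -> None:
    np.savetxt(Path(path), np.asarray(times_s), header="time_s", fmt="%.9f")


def read_arrival_times(path) -> np.ndarray:
    return np.loadtxt(Path(path))


def write_correlation(path, curve: CorrelationCurve) -> None:
    np.savetxt(Path(path), np.column_stack([curve.lags_ms, curve.g]),
               header="lag_ms G", fmt="%.9g")


def read_correlation(path) -> CorrelationCurve:
    data = np.loadtxt(Path(path))
    return CorrelationCurve(lags_ms=data[:, 0], g=data[:, 1])


def write_scaling_table(path, variant_ids, n_res, re_nm, sigma_nm=None) -> None:
    df = pd.DataFrame({"variant_id": variant_ids, "N_res": n_res, "R_E_nm": re_nm})
    if sigma_nm is not None:
        df["sigma_nm"] = sigma_nm
    df.to_csv(Path(path), sep="\t", index=False)


def read_scaling_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_burst_table(path, bursts: list[Burst], es_pairs=None) -> None:
    rows = []
    for k, b in enumerate(bursts):
        row = {"start_s": b.start, "stop_s": b.stop, "n_photons": b.n_photons,
               "I_DD": b.i_dd, "I_DA": b.i_da, "I_AA": b.i_aa}
        if es_pairs is not None:
            row["E"], row["S"] = es_pairs[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def write_xyz(path, traj: TrajectoryFrames, element: str = "C",
              manifest: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        n = traj.coords.shape[1]
        for f in range(traj.n_frames):
            fh.write(f"{n}\nframe {f}\n")
            for x, y, z in traj.coords[f]:
                fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")
    meta = {"box_a": traj.box, "frame_interval_ps": traj.frame_interval_ps}
    if manifest:
        meta.update(manifest)
    _sidecar(path).write_text(json.dumps(meta))


def read_xyz(path) -> TrajectoryFrames:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frames = []
    with path.open() as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            fh.readline()
            xyz = np.array(
                [fh.readline().split()[1:4] for _ in range(n)], dtype=float
            )
            frames.append(xyz)
    return TrajectoryFrames(coords=np.asarray(frames), box=float(meta["box_a"]),
                            frame_interval_ps=float(meta["frame_interval_ps"]))


def read_fasta_sequence(path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq)


def read_pdb_ca_coords(path, chain_id: str | None = None) -> dict:
    """C-alpha coordinates (A) per residue position index from a PDB file.

    Returns a 0-based {index: (x, y, z)} mapping in residue order, ready to
    feed :func:`idpscale.cg_sim.topology.build_topology` as structured-region
    coordinates (offset the keys to the region's position in the construct).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    coords = {}
    k = 0
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for res in chain:
            if "CA" in res:
                coords[k] = tuple(float(v) for v in res["CA"].coord)
                k += 1
    return coords
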