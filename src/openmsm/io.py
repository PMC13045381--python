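"""File formats: PDB frames, the feature container, fixtures and tables.

Coordinates travel as multi-model PDB (read through biotite, with
chain/residue labels mapped to protein-domain labels via a user-supplied
residue-range table).  Feature trajectories are stored as a directory of
flat little-endian float64 binaries plus a JSON manifest -- a
language-neutral, streamable container.  Matrices go to labelled
delimited text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .featurize import FeatureTrajectory
from .synthetic import KineticFixture, StructureFrame

# standard atomic masses for mass-weighted centroids on real input
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


def read_pdb_frames(
    path,
    domain_ranges: dict | None = None,
    membrane_slab=(0.0, 40.0, 100.0),
) -> list[StructureFrame]:
    """Read a (multi-model) PDB file into labelled structure frames.

    ``domain_ranges`` maps a domain label to an inclusive residue-id range
    ``(lo, hi)``; residues outside every range are labelled ``"other"``
    (with a warning).  Standard lipid residue names (POPC/POPS) map to
    their species; every distinct chain becomes one molecule id.
    """
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames = []
    first = stack[0]
    chain_ids = {c: i for i, c in enumerate(dict.fromkeys(first.chain_id))}

    def classify(res_id, res_name):
        lipid_alias = {"POPC": "POPC", "PC": "POPC", "POPS": "POPS", "PS": "POPS"}
        if res_name in lipid_alias:
            return lipid_alias[res_name]
        if domain_ranges:
            for dom, (lo, hi) in domain_ranges.items():
                if lo <= res_id <= hi:
                    return dom
        return "other"

    classes = np.array(
        [classify(int(r), str(n)) for r, n in zip(first.res_id, first.res_name)], dtype=object
    )
    if domain_ranges and (classes == "other").any():
        import warnings

        warnings.warn(
            f"{int((classes == 'other').sum())} atoms fell outside every domain range; "
            "labelled 'other'",
            RuntimeWarning,
            stacklevel=2,
        )
    masses = np.array([_MASSES.get(str(e).upper(), 12.011) for e in first.element])
    mol_id = np.array([chain_ids[c] for c in first.chain_id])
    for model in stack:
        frames.append(
            StructureFrame(
                coords=np.asarray(model.coord, dtype=float),
                residue_id=np.asarray(first.res_id, dtype=int),
                residue_name=np.asarray(first.res_name, dtype=object),
                molecule_id=mol_id.copy(),
                molecule_class=classes.copy(),
                membrane_slab=tuple(membrane_slab),
                masses=masses.copy(),
            )
        )
    return frames


def write_pdb_frames(frames, path) -> None:
    """Write structure frames as a multi-model PDB (pseudo-atoms as CA)."""
    frames = frames if isinstance(frames, list) else [frames]
    ref = frames[0]
    arrays = []
    for fr in frames:
        arr = struc.AtomArray(fr.n_atoms)
        arr.coord = np.asarray(fr.coords, dtype=np.float32)
        # one chain letter per molecule class, contiguous in the file, so
        # hierarchy-based parsers keep the original atom order
        class_letter = {}
        chains = []
        for c in fr.molecule_class:
            if c not in class_letter:
                class_letter[c] = chr(ord("A") + len(class_letter) % 26)
            chains.append(class_letter[c])
        arr.chain_id = np.array(chains, dtype="U4")
        arr.res_id = np.asarray(fr.residue_id, dtype=int)
        # PDB residue names are limited to 3 characters; lipids keep a
        # recognizable short alias so the reader can restore the species
        short = {"POPC": "PC", "POPS": "PS", "FabH": "FBH", "FabL": "FBL"}
        arr.res_name = np.array(
            [short.get(str(r), str(r)[:3]) for r in fr.residue_name], dtype="U5"
        )
        # distinct atom names within a residue, or downstream parsers
        # may drop apparent duplicates
        names = []
        counter = {}
        for rid in fr.residue_id:
            k = counter.get(rid, 0) + 1
            counter[rid] = k
            names.append("CA" if k == 1 else f"C{k}")
        arr.atom_name = np.array(names, dtype="U6")
        arr.element = np.full(fr.n_atoms, "C", dtype="U2")
        arrays.append(arr)
    f = pdb.PDBFile()
    f.set_structure(struc.stack(arrays) if len(arrays) > 1 else arrays[0])
    f.write(str(path))
    _ = ref


def write_feature_container(trajs: list[FeatureTrajectory], directory, labels=None) -> None:
    """Write feature trajectories as flat float64 binaries + JSON manifest.

    ``labels`` optionally adds a per-frame integer label column file per
    trajectory (ground truth held out from the pipeline, for tests only).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"dtype": "<f8", "frame_interval_ns": trajs[0].frame_interval,
                "feature_names": list(trajs[0].feature_names), "trajectories": []}
    for i, t in enumerate(trajs):
        name = f"traj_{i:04d}.bin"
        np.asarray(t.values, dtype="<f8").tofile(directory / name)
        entry = {"file": name, "shape": list(t.values.shape)}
        if labels is not None:
            lname = f"traj_{i:04d}.labels.bin"
            np.asarray(labels[i], dtype="<i8").tofile(directory / lname)
            entry["labels_file"] = lname
        manifest["trajectories"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_feature_container(directory) -> list[FeatureTrajectory]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest["trajectories"]:
        values = np.fromfile(directory / entry["file"], dtype=manifest["dtype"]).reshape(
            entry["shape"]
        )
        out.append(
            FeatureTrajectory(values, manifest["frame_interval_ns"], manifest["feature_names"])
        )
    return out


def write_fixture_json(fixture: KineticFixture, path) -> None:
    Path(path).write_text(json.dumps(fixture.to_json_dict(), indent=1))


def read_fixture_json(path) -> KineticFixture:
    d = json.loads(Path(path).read_text())
    return KineticFixture(
        name=d["name"],
        state_names=tuple(d["state_names"]),
        transition_matrix=np.asarray(d["transition_matrix"]),
        stationary=np.asarray(d["stationary"]),
        frame_interval=d["frame_interval_ns"],
        emission_means=np.asarray(d["emission_means"]),
        emission_sds=np.asarray(d["emission_sds"]),
        ar_coefficient=d["ar_coefficient"],
        accessibility_dim=d["accessibility_dim"],
    )


def write_labeled_matrix(matrix: np.ndarray, path, row_labels=None, col_labels=None) -> None:
    """Delimited-text matrix with optional row/column labels."""
    matrix = np.asarray(matrix)
    lines = []
    if col_labels is not None:
        lines.append("\t".join([""] + [str(c) for c in col_labels]))
    for i, row in enumerate(matrix):
        prefix = [str(row_labels[i])] if row_labels is not None else []
        lines.append("\t".join(prefix + [f"{v:.10g}" for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def array_checksum(arr: np.ndarray) -> str:
    """Stable content hash of an array (shape + little-endian bytes)."""
    arr = np.ascontiguousarray(arr)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()[:16]
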