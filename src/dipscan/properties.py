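"""Recipient and motif biophysical feature computation.

Sequence features are windowed sums of published amino-acid scales;
structural features (backbone dihedrals, Shrake-Rupley solvent-accessible
surface area, heavy-atom contact density) come from a structure model
backed by a biotite ``AtomArray``. ANM stiffness/fluctuation profiles from
:mod:`dipscan.anm` and externally supplied RMSF / secondary-structure
annotations assemble into one recipient table (positions x features) and
one motif table (motifs x features).

Recipient windows are anchored before / centered on / after the insertion
site ("after residue i") with lengths 1, 3, 5, 7, 9, 11; motif features are
whole-sequence sums plus N-/C-terminal window sums of lengths 1-6. Windows
truncated at the chain termini sum over the available residues and are
flagged in the result's ``attrs['truncated']``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .scales import SCALE_NAMES, scale_values

__all__ = [
    "StructureModel", "WindowSpec", "windowed_scale_scores",
    "motif_scale_scores", "contact_density", "backbone_and_surface",
    "assemble_feature_table", "read_pdb",
]

RECIPIENT_WINDOWS = (1, 3, 5, 7, 9, 11)
MOTIF_TERMINAL_WINDOWS = (1, 2, 3, 4, 5, 6)
ANCHORS = ("before", "centered", "after")

_ELEMENT_POLAR = {"N", "O"}


@dataclass(frozen=True)
class WindowSpec:
    """Window scheme for aggregating per-residue values around a site."""
    anchors: tuple = ANCHORS
    lengths: tuple = RECIPIENT_WINDOWS

    def __post_init__(self):
        bad = [w for w in self.lengths if w < 1]
        if bad:
            raise ValueError(f"window lengths must be positive, got {bad}")
        unknown = set(self.anchors) - set(ANCHORS)
        if unknown:
            raise ValueError(f"unknown anchors: {sorted(unknown)}")


@dataclass
class StructureModel:
    """A recipient (or motif) structure: biotite atoms plus position map."""
    atoms: "struc.AtomArray"
    # map from insertion-profile position -> res_id in the structure
    numbering: dict[int, int] | None = None

    def res_id_for(self, position: int) -> int:
        if self.numbering is None:
            return position
        try:
            return self.numbering[position]
        except KeyError:
            raise KeyError(f"position {position} not covered by the "
                           "structure numbering map") from None

    @property
    def ca_coords(self) -> np.ndarray:
        ca = self.atoms[self.atoms.atom_name == "CA"]
        order = np.argsort(ca.res_id, kind="stable")
        return ca.coord[order]

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.atoms.res_id)


def read_pdb(path, chain: str | None = None, model: int = 1) -> StructureModel:
    """Load the first (or selected) model of a PDB file, protein atoms only."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model)
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[atoms.element != "H"]
    if atoms.array_length() == 0:
        raise ValueError(f"no protein atoms in {path} (chain={chain!r})")
    return StructureModel(atoms=atoms)


# --------------------------------------------------------------------------
# sequence windows


def _window_bounds(position: int, anchor: str, length: int) -> tuple[int, int]:
    """1-based inclusive residue range of a window at an insertion site
    ("after residue ``position``")."""
    if anchor == "before":
        return position - length + 1, position
    if anchor == "after":
        return position + 1, position + length
    half = (length - 1) // 2
    return position - half, position + (length - 1) - half


def windowed_scale_scores(sequence: str, scale_name: str,
                          window_spec: WindowSpec | None = None,
                          fallback: float | None = None) -> pd.DataFrame:
    """Recipient windowed sums of one amino-acid scale.

    Returns a positions x columns frame (one column per anchor x length,
    named ``{scale}_{anchor}{length}``). Truncated windows sum over the
    available residues; the set of truncated (position, column) pairs is
    in ``attrs['truncated']``.
    """
    spec = window_spec or WindowSpec()
    values = np.asarray(scale_values(sequence, scale_name, fallback=fallback))
    n = len(values)
    positions = range(1, n + 1)
    data, truncated = {}, set()
    for anchor in spec.anchors:
        for w in spec.lengths:
            col = f"{scale_name}_{anchor}{w}"
            sums = np.empty(n)
            for k, pos in enumerate(positions):
                lo, hi = _window_bounds(pos, anchor, w)
                lo_c, hi_c = max(lo, 1), min(hi, n)
                if lo_c > hi_c:
                    sums[k] = 0.0
                    truncated.add((pos, col))
                    continue
                if lo_c != lo or hi_c != hi:
                    truncated.add((pos, col))
                sums[k] = values[lo_c - 1:hi_c].sum()
            data[col] = sums
    out = pd.DataFrame(data, index=pd.Index(positions, name="position"))
    out.attrs["truncated"] = truncated
    return out


def motif_scale_scores(sequence: str, scale_name: str,
                       terminal_lengths: tuple = MOTIF_TERMINAL_WINDOWS,
                       fallback: float | None = None) -> dict[str, float]:
    """Motif features: whole-sequence sum plus N-/C-terminal window sums."""
    values = np.asarray(scale_values(sequence, scale_name, fallback=fallback))
    out = {f"{scale_name}_whole": float(values.sum())}
    for w in terminal_lengths:
        out[f"{scale_name}_nterm{w}"] = float(values[:w].sum())
        out[f"{scale_name}_cterm{w}"] = float(values[-w:].sum())
    return out


# --------------------------------------------------------------------------
# structure-derived features


def contact_density(structure: StructureModel, position: int | None = None,
                    heavy_atom_cutoff: float = 4.5):
    """Inter-residue heavy-atom contact count per residue.

    Counts atom pairs within ``heavy_atom_cutoff`` angstroms between a
    residue and residues at sequence separation >= 2 (i and i+-1 excluded).
    Returns a Series over residues, or a single count for ``position``.
    """
    atoms = structure.atoms[structure.atoms.element != "H"]
    coords = atoms.coord
    res = atoms.res_id
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    pairs = tree.query_pairs(heavy_atom_cutoff, output_type="ndarray")
    counts: dict[int, int] = {int(r): 0 for r in np.unique(res)}
    for a, b in pairs:
        ra, rb = int(res[a]), int(res[b])
        if abs(ra - rb) >= 2:
            counts[ra] += 1
            counts[rb] += 1
    series = pd.Series(counts).sort_index()
    series.index.name = "res_id"
    if position is not None:
        rid = structure.res_id_for(position)
        if rid not in series.index:
            return np.nan
        return int(series.loc[rid])
    return series


def backbone_and_surface(structure: StructureModel,
                         probe_radius: float = 1.4,
                         point_number: int = 1000,
                         secondary_structure: pd.Series | None = None
                         ) -> pd.DataFrame:
    """Per-residue phi/psi (degrees), SASA split, and secondary structure.

    SASA uses the Shrake-Rupley sphere-point method with element-based
    radii; the polar/nonpolar split assigns N/O atoms to the polar class.
    Secondary-structure content flags come from an annotation Series
    (res_id -> {'H','E','C'}) when provided; otherwise the columns are
    missing values.
    """
    atoms = structure.atoms
    res_ids = structure.residue_ids
    out = pd.DataFrame(index=pd.Index(res_ids, name="res_id"))

    phi, psi, _ = struc.dihedral_backbone(atoms)
    # biotite returns one value per residue (NaN at chain ends)
    out["phi"] = np.degrees(phi)
    out["psi"] = np.degrees(psi)

    sasa = struc.sasa(atoms, probe_radius=probe_radius,
                      point_number=point_number, vdw_radii="Single")
    polar_mask = np.isin(atoms.element, list(_ELEMENT_POLAR))
    total, polar, nonpolar = [], [], []
    for rid in res_ids:
        mask = atoms.res_id == rid
        s = np.nan_to_num(sasa[mask])
        total.append(s.sum())
        polar.append(s[polar_mask[mask]].sum())
        nonpolar.append(s[~polar_mask[mask]].sum())
    out["sasa_total"] = total
    out["sasa_polar"] = polar
    out["sasa_nonpolar"] = nonpolar

    if secondary_structure is not None:
        ss = secondary_structure.reindex(res_ids)
        out["is_helix"] = (ss == "H").astype(float).where(ss.notna())
        out["is_sheet"] = (ss == "E").astype(float).where(ss.notna())
    else:
        out["is_helix"] = np.nan
        out["is_sheet"] = np.nan
    return out


# --------------------------------------------------------------------------
# assembly


def _merge_parts(parts, key_name: str) -> pd.DataFrame:
    merged = None
    for part in parts:
        df = part.copy()
        df.index.name = key_name
        if merged is None:
            merged = df
            continue
        dup = set(merged.columns) & set(df.columns)
        if dup:
            raise ValueError(f"duplicate feature names across sources: "
                             f"{sorted(dup)}")
        unmatched = set(df.index) ^ set(merged.index)
        if unmatched:
            raise ValueError(
                f"{key_name} keys do not match across sources; "
                f"unmatched: {sorted(unmatched)[:10]}")
        merged = merged.join(df, how="inner")
    if merged is None:
        raise ValueError("no feature sources supplied")
    return merged


def assemble_feature_table(recipient_parts, motif_parts):
    """Join per-source feature frames into the recipient/motif tables.

    Each part is a DataFrame indexed by position (recipient) or motif id
    (motif). Duplicate feature names or mismatched keys are rejected.
    Returns ``(recipient_table, motif_table)``; either may be None when no
    parts are given for that side.
    """
    rec = _merge_parts(recipient_parts, "position") if recipient_parts else None
    mot = _merge_parts(motif_parts, "motif_id") if motif_parts else None
    return rec, mot
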