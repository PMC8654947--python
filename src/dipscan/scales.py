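"""Per-residue amino-acid scale tables.

One published standard table per named scale. Sources:

- ``hydropathy``: Kyte & Doolittle, J Mol Biol 157:105 (1982).
- ``hydrophobicity``: Eisenberg consensus scale, J Mol Biol 179:125 (1984).
- ``alpha_helix_propensity`` / ``beta_sheet_propensity`` /
  ``reverse_turn_propensity``: Chou & Fasman, Biochemistry 13:222 (1974).
- ``polarity``: Grantham, Science 185:862 (1974).
- ``volume``: Zamyatnin, Prog Biophys Mol Biol 24:107 (1972).
- ``surface_area``: Chothia, J Mol Biol 105:1 (1976), residue ASA in Gly-X-Gly.
- ``buried_accessibility``: Janin, Nature 277:491 (1979), interior propensity.
- ``flexibility``: Bhaskaran & Ponnuswamy, Int J Pept Protein Res 32:241 (1988).
- ``molecular_weight``: free amino-acid monoisotopic-free average masses (Da).
- ``pKa``: side-chain pKa, 7.0 assigned to non-ionizable residues.
- ``negative_charge`` / ``positive_charge``: unit indicator scales (D/E; K/R/H).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _table(**kwargs: float) -> dict[str, float]:
    missing = set(AMINO_ACIDS) - set(kwargs)
    if missing:  # pragma: no cover - guards table typos at import time
        raise ValueError(f"scale table missing residues: {sorted(missing)}")
    return dict(kwargs)


SCALES: dict[str, dict[str, float]] = {
    "molecular_weight": _table(
        A=89.094, R=174.203, N=132.119, D=133.104, C=121.154, Q=146.146,
        E=147.131, G=75.067, H=155.156, I=131.175, L=131.175, K=146.189,
        M=149.208, F=165.192, P=115.132, S=105.093, T=119.119, W=204.228,
        Y=181.191, V=117.148,
    ),
    "surface_area": _table(
        A=115.0, R=225.0, N=160.0, D=150.0, C=135.0, Q=180.0, E=190.0,
        G=75.0, H=195.0, I=175.0, L=170.0, K=200.0, M=185.0, F=210.0,
        P=145.0, S=115.0, T=140.0, W=255.0, Y=230.0, V=155.0,
    ),
    "alpha_helix_propensity": _table(
        A=1.42, R=0.98, N=0.67, D=1.01, C=0.70, Q=1.11, E=1.51, G=0.57,
        H=1.00, I=1.08, L=1.21, K=1.16, M=1.45, F=1.13, P=0.57, S=0.77,
        T=0.83, W=1.08, Y=0.69, V=1.06,
    ),
    "beta_sheet_propensity": _table(
        A=0.83, R=0.93, N=0.89, D=0.54, C=1.19, Q=1.10, E=0.37, G=0.75,
        H=0.87, I=1.60, L=1.30, K=0.74, M=1.05, F=1.38, P=0.55, S=0.75,
        T=1.19, W=1.37, Y=1.47, V=1.70,
    ),
    "buried_accessibility": _table(
        A=0.3, R=-1.4, N=-0.5, D=-0.6, C=0.9, Q=-0.7, E=-0.7, G=0.3,
        H=-0.1, I=0.7, L=0.5, K=-1.8, M=0.4, F=0.5, P=-0.3, S=-0.1,
        T=-0.2, W=0.3, Y=-0.4, V=0.6,
    ),
    "flexibility": _table(
        A=0.357, R=0.529, N=0.463, D=0.511, C=0.346, Q=0.493, E=0.497,
        G=0.544, H=0.323, I=0.462, L=0.365, K=0.466, M=0.295, F=0.314,
        P=0.509, S=0.507, T=0.444, W=0.305, Y=0.420, V=0.386,
    ),
    "hydropathy": _table(
        A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5, G=-0.4,
        H=-3.2, I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8, P=-1.6, S=-0.8,
        T=-0.7, W=-0.9, Y=-1.3, V=4.2,
    ),
    "hydrophobicity": _table(
        A=0.62, R=-2.53, N=-0.78, D=-0.90, C=0.29, Q=-0.85, E=-0.74,
        G=0.48, H=-0.40, I=1.38, L=1.06, K=-1.50, M=0.64, F=1.19, P=0.12,
        S=-0.18, T=-0.05, W=0.81, Y=0.26, V=1.08,
    ),
    "negative_charge": _table(
        A=0.0, R=0.0, N=0.0, D=1.0, C=0.0, Q=0.0, E=1.0, G=0.0, H=0.0,
        I=0.0, L=0.0, K=0.0, M=0.0, F=0.0, P=0.0, S=0.0, T=0.0, W=0.0,
        Y=0.0, V=0.0,
    ),
    "pKa": _table(
        A=7.0, R=12.48, N=7.0, D=3.65, C=8.3, Q=7.0, E=4.25, G=7.0,
        H=6.0, I=7.0, L=7.0, K=10.53, M=7.0, F=7.0, P=7.0, S=7.0, T=7.0,
        W=7.0, Y=10.07, V=7.0,
    ),
    "polarity": _table(
        A=8.1, R=10.5, N=11.6, D=13.0, C=5.5, Q=10.5, E=12.3, G=9.0,
        H=10.4, I=5.2, L=4.9, K=11.3, M=5.7, F=5.2, P=8.0, S=9.2, T=8.6,
        W=5.4, Y=6.2, V=5.9,
    ),
    "positive_charge": _table(
        A=0.0, R=1.0, N=0.0, D=0.0, C=0.0, Q=0.0, E=0.0, G=0.0, H=1.0,
        I=0.0, L=0.0, K=1.0, M=0.0, F=0.0, P=0.0, S=0.0, T=0.0, W=0.0,
        Y=0.0, V=0.0,
    ),
    "reverse_turn_propensity": _table(
        A=0.66, R=0.95, N=1.56, D=1.46, C=1.19, Q=0.98, E=0.74, G=1.56,
        H=0.95, I=0.47, L=0.59, K=1.01, M=0.60, F=0.60, P=1.52, S=1.43,
        T=0.96, W=0.96, Y=1.14, V=0.50,
    ),
    "volume": _table(
        A=88.6, R=173.4, N=114.1, D=111.1, C=108.5, Q=143.8, E=138.4,
        G=60.1, H=153.2, I=166.7, L=166.7, K=168.6, M=162.9, F=189.9,
        P=112.7, S=89.0, T=116.1, W=227.8, Y=193.6, V=140.0,
    ),
}

SCALE_NAMES = tuple(SCALES)


def scale_values(sequence: str, scale_name: str,
                 fallback: float | None = None) -> list[float]:
    """Map a protein sequence to per-residue values of a named scale.

    Unknown residues raise ``KeyError`` unless ``fallback`` is given.
    """
    try:
        table = SCALES[scale_name]
    except KeyError:
        raise KeyError(
            f"unknown scale {scale_name!r}; available: {sorted(SCALES)}"
        ) from None
    out = []
    for aa in sequence.upper():
        if aa in table:
            out.append(table[aa])
        elif fallback is not None:
            out.append(fallback)
        else:
            raise KeyError(f"residue {aa!r} not in scale {scale_name!r} "
                           "and no fallback configured")
    return out
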