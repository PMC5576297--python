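"""Feature encoders: PSSM-RT blocks plus sequence and physicochemical blocks.

The PSSM-RT encoding of a residue instance with window size w consists of

* conservation — the w x 20 window of logistic-normalised scores, flattened;
* pair relationships — for every ordered amino-acid pair (r1, r2), the sum
  over the w-1 context positions j of S(N)[target, r2] * S(N)[j, r1]
  (400 values);
* multi relationships — for every amino acid r, the summed normalised score
  over the left half-window including the target, and likewise over the
  right half-window (20 + 20 values).

Total PSSM-RT dimension: 20*w + 400 + 40.  Two further blocks encode
window composition / predicted structure tracks, and eight tabulated
physicochemical properties per window position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pssmrt.pssm import AA_INDEX, PSSM_COLUMNS, PAD_CHAR, ResidueInstance

logger = logging.getLogger(__name__)
_warned_chains: set[str] = set()

SS_STATES = "HEC"  # helix, strand, coil — PSIPRED's three states


# ---------------------------------------------------------------------------
# feature schema plumbing

@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature blocks with names, lengths and slot labels."""

    blocks: tuple[tuple[str, int], ...]

    @property
    def length(self) -> int:
        return sum(n for _, n in self.blocks)

    def offset(self, name: str) -> tuple[int, int]:
        """Return (start, stop) of a named block within the flat vector."""
        start = 0
        for block, n in self.blocks:
            if block == name:
                return start, start + n
            start += n
        raise KeyError(f"schema has no block {name!r}")

    def slot_names(self) -> list[str]:
        names: list[str] = []
        for block, n in self.blocks:
            if block == "conservation":
                w = n // 20
                names += [f"cons_p{p}_{aa}" for p in range(w) for aa in PSSM_COLUMNS]
            elif block == "pair":
                names += [f"pair_{r1}_{r2}" for r1 in PSSM_COLUMNS for r2 in PSSM_COLUMNS]
            elif block == "multi_left":
                names += [f"mleft_{aa}" for aa in PSSM_COLUMNS]
            elif block == "multi_right":
                names += [f"mright_{aa}" for aa in PSSM_COLUMNS]
            else:
                names += [f"{block}_{k}" for k in range(n)]
        return names


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if len(self.values) != self.schema.length:
            raise ValueError(
                f"vector length {len(self.values)} does not match schema length {self.schema.length}"
            )

    def block(self, name: str) -> np.ndarray:
        a, b = self.schema.offset(name)
        return self.values[a:b]


def pssm_rt_schema(w: int) -> FeatureSchema:
    return FeatureSchema(
        (("conservation", 20 * w), ("pair", 400), ("multi_left", 20), ("multi_right", 20))
    )


def sequence_schema(w: int) -> FeatureSchema:
    # composition(20) | ss one-hot(3w) | accessibility(w) | target identity(20)
    return FeatureSchema((("sequence", 40 + 4 * w),))


def physicochemical_schema(w: int) -> FeatureSchema:
    return FeatureSchema((("physicochemical", 8 * w),))


# ---------------------------------------------------------------------------
# PSSM-RT blocks

def encode_conservation(inst: ResidueInstance) -> np.ndarray:
    """Row-major flattening of the normalised window (20*w values)."""
    return inst.window.ravel().copy()


def encode_pair_relationships(inst: ResidueInstance) -> np.ndarray:
    """Summed pairwise products between the target row and its context rows.

    Entry for the ordered pair (r1, r2) — row-major, r1 outer — is
    ``S(N)[target, r2] * sum_j S(N)[j, r1]`` over the w-1 context
    positions j.  Padded rows are zero-filled and contribute nothing.
    """
    target = inst.window[inst.half]
    context_sum = inst.window.sum(axis=0) - target
    return np.outer(context_sum, target).ravel()


def encode_multi_relationships(inst: ResidueInstance) -> tuple[np.ndarray, np.ndarray]:
    """Summed normalised scores over the left / right half-windows.

    Both sums include the target row, so on an unpadded window each of
    the 20 entries lies in [0, (w+1)/2].
    """
    left = inst.window[: inst.half + 1].sum(axis=0)
    right = inst.window[inst.half :].sum(axis=0)
    return left, right


def assemble_pssm_rt(inst: ResidueInstance) -> FeatureVector:
    """Concatenate conservation | pair | multi_left | multi_right (20w+440 values)."""
    left, right = encode_multi_relationships(inst)
    values = np.concatenate(
        [encode_conservation(inst), encode_pair_relationships(inst), left, right]
    )
    return FeatureVector(values, pssm_rt_schema(inst.window_size))


# ---------------------------------------------------------------------------
# sequence features

def encode_sequence_features(
    inst: ResidueInstance,
    ss: np.ndarray | None = None,
    acc: np.ndarray | None = None,
    chain_length: int | None = None,
) -> FeatureVector:
    """Window composition, predicted-structure tracks and target identity.

    ``ss`` is an L x 3 per-position probability (or one-hot) matrix in the
    H/E/C state order, ``acc`` an L-vector of relative solvent
    accessibilities; both are optional and emit zeros when absent.
    """
    w, half, i = inst.window_size, inst.half, inst.target_position
    for name, track, width in (("ss", ss, 2), ("acc", acc, 1)):
        if track is not None and chain_length is not None and len(track) != chain_length:
            raise ValueError(
                f"{name} track length {len(track)} does not match chain length {chain_length}"
            )
    composition = np.zeros(20)
    n_real = 0
    for letter in inst.residues:
        if letter == PAD_CHAR:
            continue
        n_real += 1
        if letter in AA_INDEX:
            composition[AA_INDEX[letter]] += 1
    if n_real:
        composition /= n_real

    ss_block = np.zeros((w, 3))
    acc_block = np.zeros(w)
    if (ss is None or acc is None) and inst.chain_id not in _warned_chains:
        _warned_chains.add(inst.chain_id)
        logger.warning(
            "chain %s: missing %s track(s); emitting zeros",
            inst.chain_id,
            " and ".join(n for n, t in (("ss", ss), ("acc", acc)) if t is None),
        )
    for k in range(w):
        pos = i - half + k
        if inst.pad_mask[k] or not 1 <= pos:
            continue
        if ss is not None and pos <= len(ss):
            ss_block[k] = ss[pos - 1]
        if acc is not None and pos <= len(acc):
            acc_block[k] = acc[pos - 1]

    identity = np.zeros(20)
    if inst.target_residue in AA_INDEX:
        identity[AA_INDEX[inst.target_residue]] = 1.0

    values = np.concatenate([composition, ss_block.ravel(), acc_block, identity])
    return FeatureVector(values, sequence_schema(w))


# ---------------------------------------------------------------------------
# physicochemical features

PROPERTY_NAMES = (
    "pka_amino",
    "pka_carboxyl",
    "eiip",
    "lone_electron_pairs",
    "wiener_index",
    "molecular_mass",
    "pka_side_chain",
    "hydrophobicity",
)

# Eight tabulated properties per amino acid:
#   pKa of the alpha-amino and alpha-carboxyl groups and of the side chain
#   (CRC Handbook; 0 where the side chain has no ionisable proton),
#   electron-ion interaction potential (Veljkovic),
#   lone electron pairs on side-chain heteroatoms,
#   Wiener index of the heavy-atom molecular graph,
#   free amino-acid molecular mass (Da),
#   Kyte-Doolittle hydrophobicity.
_PROPERTY_DATA = {
    #      NH3+   COOH   EIIP   LEP  Wiener  mass    side   KD
    "A": (9.69, 2.34, 0.0373, 0, 29, 89.09, 0.00, 1.8),
    "R": (9.04, 2.17, 0.0959, 3, 247, 174.20, 12.48, -4.5),
    "N": (8.80, 2.02, 0.0036, 3, 96, 132.12, 0.00, -3.5),
    "D": (9.60, 1.88, 0.1263, 4, 96, 133.10, 3.65, -3.5),
    "C": (10.28, 1.96, 0.0829, 2, 46, 121.16, 8.18, 2.5),
    "Q": (9.13, 2.17, 0.0761, 3, 136, 146.15, 0.00, -3.5),
    "E": (9.67, 2.19, 0.0058, 4, 136, 147.13, 4.25, -3.5),
    "G": (9.60, 2.34, 0.0050, 0, 18, 75.07, 0.00, -0.4),
    "H": (9.17, 1.82, 0.0242, 2, 165, 155.16, 6.00, -3.2),
    "I": (9.60, 2.36, 0.0000, 0, 92, 131.17, 0.00, 4.5),
    "L": (9.60, 2.36, 0.0000, 0, 96, 131.17, 0.00, 3.8),
    "K": (8.95, 2.18, 0.0371, 1, 143, 146.19, 10.53, -3.9),
    "M": (9.21, 2.28, 0.0823, 2, 102, 149.21, 0.00, 1.9),
    "F": (9.13, 1.83, 0.0946, 0, 212, 165.19, 0.00, 2.8),
    "P": (10.60, 1.99, 0.0198, 0, 62, 115.13, 0.00, -1.6),
    "S": (9.15, 2.21, 0.0829, 2, 46, 105.09, 0.00, -0.8),
    "T": (9.10, 2.09, 0.0941, 2, 65, 119.12, 0.00, -0.7),
    "W": (9.39, 2.83, 0.0548, 1, 369, 204.23, 0.00, -0.9),
    "Y": (9.11, 2.20, 0.0516, 2, 268, 181.19, 10.07, -1.3),
    "V": (9.62, 2.32, 0.0057, 0, 65, 117.15, 0.00, 4.2),
}


@dataclass(frozen=True)
class PropertyTable:
    """20 x 8 table of amino-acid properties with min-max scaling bounds."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [aa for aa in PSSM_COLUMNS if aa not in self.table.index]
        if missing:
            raise ValueError(f"property table missing amino acids {missing}")
        if list(self.table.columns) != list(PROPERTY_NAMES):
            raise ValueError(f"property table must have columns {PROPERTY_NAMES}")
        if not np.all(np.isfinite(self.table.to_numpy())):
            raise ValueError("property table contains non-finite values")

    @classmethod
    def default(cls) -> "PropertyTable":
        df = pd.DataFrame.from_dict(_PROPERTY_DATA, orient="index", columns=PROPERTY_NAMES)
        return cls(df.loc[list(PSSM_COLUMNS)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PropertyTable":
        return cls(pd.read_csv(path, index_col=0))

    def scaled(self) -> np.ndarray:
        """Property values min-max scaled to [0, 1] over the 20 amino acids."""
        raw = self.table.loc[list(PSSM_COLUMNS)].to_numpy(dtype=float)
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (raw - lo) / span


DEFAULT_PROPERTY_TABLE = PropertyTable.default()


def encode_physicochemical(
    inst: ResidueInstance, table: PropertyTable = DEFAULT_PROPERTY_TABLE
) -> FeatureVector:
    """Eight scaled property values per window position (8*w values).

    Padded positions and 'X' residues emit zeros.
    """
    scaled = table.scaled()
    w = inst.window_size
    values = np.zeros((w, 8))
    for k, letter in enumerate(inst.residues):
        if letter in AA_INDEX:
            values[k] = scaled[AA_INDEX[letter]]
    return FeatureVector(values.ravel(), physicochemical_schema(w))


# ---------------------------------------------------------------------------
# prediction-track readers

def read_ss2(path: str | Path) -> np.ndarray:
    """Read a PSIPRED .ss2 file into an L x 3 probability matrix (H/E/C order).

    PSIPRED writes per-position columns in C, H, E order; they are
    re-ordered here.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        tokens = line.split()
        if len(tokens) >= 6 and tokens[0].isdigit():
            c, h, e = (float(t) for t in tokens[3:6])
            rows.append((h, e, c))
    if not rows:
        raise ValueError(f"{path}: no prediction rows found")
    return np.array(rows)


def read_sable(path: str | Path) -> np.ndarray:
    """Read a SABLE solvent-accessibility output into an L-vector in [0, 1].

    Accepts the plain-text per-residue table (position, residue, value);
    values on a 0-100 scale are divided by 100.
    """
    vals = []
    for line in Path(path).read_text().splitlines():
        tokens = line.split()
        if len(tokens) >= 3 and tokens[0].isdigit():
            vals.append(float(tokens[2]))
    if not vals:
        raise ValueError(f"{path}: no accessibility rows found")
    arr = np.array(vals)
    if arr.max() > 1.0:
        arr = arr / 100.0
    return arr


def write_feature_table(
    vectors: list[FeatureVector], path: str | Path, ids: list[str] | None = None
) -> None:
    """Write feature vectors as TSV with one named column per feature slot."""
    if not vectors:
        raise ValueError("no feature vectors to write")
    schema = vectors[0].schema
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=schema.slot_names(), index=ids
    )
    df.to_csv(path, sep="\t", index=ids is not None)
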