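"""Synthetic PSSMs, labelled datasets with planted pair signal, toy complexes.

Real inputs to the predictor are PSI-BLAST profiles of protein-DNA
complex chains; at development scale those are emulated here.  A
background PSSM draws integer log-odds scores from a discretised normal
(mean 0, sd 3, clipped to [-10, 10], matching the typical range of
PSI-BLAST log-odds).  A labelled dataset plants an evolutionary
pair-relationship signal: at binding positions the target row is
shifted by +delta in one amino-acid column and nearby context rows in a
second column, so the (context, target) pair feature carries the class
signal.  Class imbalance is controlled by rho = negatives per positive;
the benchmarks this emulates run from about 1:5 to 1:14.  Toy
protein-DNA complexes realise requested residue-to-DNA minimum
distances exactly, for exercising the 3.5-Angstrom labelling rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from pssmrt.pssm import AA_INDEX, PSSM_COLUMNS, ProteinChain, Pssm, write_pssm

_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class SignalSpec:
    """Planted-signal description for a synthetic labelled dataset.

    effect_size:
        Raw-score shift delta added at signal rows/columns; 0 plants no
        signal (null data).
    pair:
        (r1, r2) — context rows are enriched in column r1, the target
        row in column r2, so the pair feature (r1, r2) discriminates.
    imbalance:
        rho = expected negatives per positive (binding fraction
        1/(rho+1)); benchmark complexes run from about 5 to 14.
    noise_sd:
        Standard deviation of the background integer scores.
    signal_radius:
        Context rows within this many positions of a binding residue
        receive the r1-column shift.
    seq_temperature:
        Softmax temperature linking residue identity to the profile:
        the letter at each position is drawn with probability
        proportional to exp(score/T), as in real profiles where the
        native residue usually scores high.  Large T approaches a
        uniform draw.
    """

    effect_size: float = 6.0
    pair: tuple[str, str] = ("R", "K")
    imbalance: float = 5.0
    noise_sd: float = 3.0
    signal_radius: int = 2
    seq_temperature: float = 2.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.imbalance < 1:
            raise ValueError("imbalance must be >= 1")
        for aa in self.pair:
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino acid {aa!r} in signal pair")


def gen_pssm(
    L: int,
    seed: int,
    mean: float = 0.0,
    sd: float = 3.0,
    clip: tuple[int, int] = (-10, 10),
    chain_id: str = "synthetic",
) -> tuple[ProteinChain, Pssm]:
    """Background chain + PSSM: uniform random sequence, discretised-normal scores."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(PSSM_COLUMNS), size=L))
    scores = np.clip(np.rint(rng.normal(mean, sd, size=(L, 20))), *clip).astype(np.int64)
    chain = ProteinChain(chain_id, seq)
    return chain, Pssm(chain_id, scores, seq)


@dataclass(frozen=True)
class SyntheticDataset:
    chains: tuple[ProteinChain, ...]
    pssms: tuple[Pssm, ...]
    labels: dict[str, np.ndarray]  # chain_id -> bool array, True = binding
    spec: SignalSpec
    seed: int

    @property
    def n_residues(self) -> int:
        return sum(c.length for c in self.chains)

    @property
    def n_positives(self) -> int:
        return int(sum(lab.sum() for lab in self.labels.values()))


def gen_labeled_dataset(
    n_chains: int,
    length_range: tuple[int, int],
    spec: SignalSpec,
    seed: int,
) -> SyntheticDataset:
    """Chains + PSSMs + labels with the planted pair-relationship signal.

    Binding positions are drawn independently with probability
    1/(rho+1).  At each binding position i, column r2 of row i is
    shifted by +delta and column r1 of the context rows within
    ``signal_radius`` of i by +delta (shifts accumulate where contexts
    overlap; shifted scores may exceed the background clip range).  The
    chain sequence is then drawn per position with probability
    proportional to exp(score/T), so residue identity — and with it the
    sequence and physicochemical feature blocks — reflects the profile
    the way native residues do.
    """
    lo, hi = length_range
    if lo < 3 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    r1, r2 = (AA_INDEX[aa] for aa in spec.pair)
    p_bind = 1.0 / (spec.imbalance + 1.0)
    letters = np.array(list(PSSM_COLUMNS))
    chains, pssms, labels = [], [], {}
    for c in range(n_chains):
        L = int(rng.integers(lo, hi + 1))
        cid = f"syn{seed}_{c:03d}"
        scores = np.clip(np.rint(rng.normal(0, spec.noise_sd, size=(L, 20))), -10, 10)
        lab = rng.random(L) < p_bind
        if spec.effect_size > 0:
            for i in np.flatnonzero(lab):
                scores[i, r2] += spec.effect_size
                j_lo = max(0, i - spec.signal_radius)
                j_hi = min(L - 1, i + spec.signal_radius)
                for j in range(j_lo, j_hi + 1):
                    if j != i:
                        scores[j, r1] += spec.effect_size
        probs = np.exp(scores / spec.seq_temperature)
        probs /= probs.sum(axis=1, keepdims=True)
        seq = "".join(letters[rng.choice(20, p=p)] for p in probs)
        chains.append(ProteinChain(cid, seq))
        pssms.append(Pssm(cid, np.rint(scores).astype(np.int64), seq))
        labels[cid] = lab
    return SyntheticDataset(tuple(chains), tuple(pssms), labels, spec, seed)


# ---------------------------------------------------------------------------
# toy protein-DNA complexes

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:^4s} {resname:>3s} {chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}"
)


def gen_toy_complex(
    geometry: list[tuple[str, float]],
    path: str | Path | None = None,
    spacing: float = 50.0,
) -> str:
    """Write a minimal PDB with one protein and one DNA chain realising the
    requested per-residue minimum distances to DNA.

    ``geometry`` lists (one-letter residue, distance in Angstrom); each
    residue is a single CA atom, faced by a DNA phosphorus at exactly
    the requested distance.  Residues are spaced far enough apart that
    only the facing DNA atom is relevant (distances must stay below the
    spacing).
    """
    lines = ["HEADER    SYNTHETIC TOY PROTEIN-DNA COMPLEX"]
    serial = 1
    for k, (res, dist) in enumerate(geometry):
        if res not in _1TO3:
            raise ValueError(f"invalid residue code {res!r}")
        if dist < 0:
            raise ValueError("distances must be >= 0")
        if dist >= spacing / 2:
            raise ValueError(f"distance {dist} too large for residue spacing {spacing}")
        lines.append(
            _PDB_ATOM.format(
                serial=serial, name="CA", resname=_1TO3[res], chain="A",
                resseq=k + 1, x=0.0, y=spacing * k, z=0.0, occ=1.0, b=0.0, elem="C",
            )
        )
        serial += 1
    lines.append("TER")
    for k, (_res, dist) in enumerate(geometry):
        lines.append(
            _PDB_ATOM.format(
                serial=serial, name="P", resname="DA", chain="B",
                resseq=k + 1, x=dist, y=spacing * k, z=0.0, occ=1.0, b=0.0, elem="P",
            )
        )
        serial += 1
    lines += ["TER", "END", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_fixture_set(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Materialise a dataset as FASTA + ASCII PSSMs + label TSV + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "chains.fasta", "w") as fh:
        for chain in dataset.chains:
            fh.write(f">{chain.chain_id}\n{chain.sequence}\n")
    for pssm in dataset.pssms:
        write_pssm(pssm, directory / f"{pssm.chain_id}.pssm")
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("chain\tposition\tlabel\n")
        for chain in dataset.chains:
            for i, is_bind in enumerate(dataset.labels[chain.chain_id], start=1):
                fh.write(f"{chain.chain_id}\t{i}\t{'+' if is_bind else '-'}\n")
    manifest = {
        "seed": dataset.seed,
        "n_chains": len(dataset.chains),
        "n_residues": dataset.n_residues,
        "n_positives": dataset.n_positives,
        "signal": {
            "effect_size": dataset.spec.effect_size,
            "pair": list(dataset.spec.pair),
            "imbalance": dataset.spec.imbalance,
            "noise_sd": dataset.spec.noise_sd,
            "signal_radius": dataset.spec.signal_radius,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_labels_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a labels TSV (chain, position, label) back into boolean arrays."""
    per_chain: dict[str, list[tuple[int, bool]]] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        cid, pos, lab = line.split("\t")
        per_chain.setdefault(cid, []).append((int(pos), lab == "+"))
    out = {}
    for cid, rows in per_chain.items():
        rows.sort()
        out[cid] = np.array([b for _, b in rows], dtype=bool)
    return out
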