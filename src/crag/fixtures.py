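"""Synthetic small-molecule corpora.

Builds random valid molecules of bounded size over the {C, N, O, F} atom set —
linear and branched skeletons with optional 3-6-membered rings and carbonyl /
hydroxyl / amine decorations — emulating the profile of small organic datasets
with up to 9 heavy atoms. Construction is graph-based (random trees with
valence bookkeeping, then RDKit sanitization), so every emitted SMILES is
valid by construction; generation is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}
_ELEMENTS = ("C", "N", "O", "F")
_WEIGHTS = (0.62, 0.16, 0.16, 0.06)


def _random_molecule(rng: np.random.Generator, max_heavy_atoms: int) -> str | None:
    n_atoms = int(rng.integers(2, max_heavy_atoms + 1))
    mol = Chem.RWMol()
    symbols: list[str] = []
    used: list[int] = []  # bonds consumed per atom

    def add_atom(sym: str) -> int:
        idx = mol.AddAtom(Chem.Atom(sym))
        symbols.append(sym)
        used.append(0)
        return idx

    def free(i: int) -> int:
        return _MAX_VALENCE[symbols[i]] - used[i]

    add_atom("C")
    for _ in range(n_atoms - 1):
        candidates = [i for i in range(len(symbols)) if free(i) >= 1]
        if not candidates:
            break
        parent = int(rng.choice(candidates))
        sym = str(rng.choice(_ELEMENTS, p=_WEIGHTS))
        child = add_atom(sym)
        mol.AddBond(parent, child, Chem.BondType.SINGLE)
        used[parent] += 1
        used[child] += 1

    # optional ring closure of size 3-6
    if rng.random() < 0.35 and len(symbols) >= 3:
        open_atoms = [i for i in range(len(symbols)) if free(i) >= 1 and symbols[i] != "F"]
        rng.shuffle(open_atoms)
        dist = Chem.GetDistanceMatrix(mol.GetMol(), force=True)
        done = False
        for a in open_atoms:
            if done:
                break
            for b in open_atoms:
                if b <= a:
                    continue
                d = int(dist[a][b])
                if 2 <= d <= 5 and mol.GetBondBetweenAtoms(a, b) is None:
                    mol.AddBond(a, b, Chem.BondType.SINGLE)
                    used[a] += 1
                    used[b] += 1
                    done = True
                    break

    # optional carbonyl decoration on a carbon with two spare valences
    if rng.random() < 0.3:
        carbons = [i for i in range(len(symbols)) if symbols[i] == "C" and free(i) >= 2]
        if carbons:
            c = int(rng.choice(carbons))
            o = add_atom("O")
            mol.AddBond(c, o, Chem.BondType.DOUBLE)
            used[c] += 2
            used[o] += 2

    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except (Chem.rdchem.MolSanitizeException, ValueError):
        return None
    if m.GetNumHeavyAtoms() > max_heavy_atoms:
        return None
    return Chem.MolToSmiles(m)


def generate_fixture_smiles(n: int, seed: int, max_heavy_atoms: int = 9) -> list[str]:
    """Generate ``n`` valid SMILES with at most ``max_heavy_atoms`` heavy atoms."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        smi = _random_molecule(rng, max_heavy_atoms)
        if smi:
            out.append(smi)
    return out
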