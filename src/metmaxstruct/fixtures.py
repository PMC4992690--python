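"""Synthetic fingerprints with planted overlap, and the embedded worked-example set.

Everything the analysis pipeline does is a function of per-pair bit counts, so
pairs constructed to have exact (a, b, c) overlap, plus random collections of
tunable density, are enough to exercise the full pipeline without any chemical
input.  Synthetic fingerprints carry the "synthetic" dialect tag so accidental
mixing with MACCS collections fails fast.

The worked-example set embeds five well-known molecules — the antipsychotics
chlorpromazine and clozapine and the metabolites thiamine (vitamin B1),
riboflavin (vitamin B2) and lumichrome (riboflavin minus its ribitol
sidechain).  The tricyclic chlorpromazine/riboflavin/lumichrome trio
illustrates why whole-molecule Tanimoto similarity can disagree with visual
substructure similarity, which is the motivating case for the asymmetric
Tversky weights.  The SMILES are taken from standard chemical references and
were verified by molecular formula and weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprints import (
    MACCS_NBITS,
    Collection,
    Fingerprint,
    MoleculeRecord,
    record_from_smiles,
)

#: id -> (SMILES, class label)
EMBEDDED_SMILES: dict[str, tuple[str, str]] = {
    "chlorpromazine": ("CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21", "drugs"),
    "clozapine": ("CN1CCN(CC1)C1=Nc2cc(Cl)ccc2Nc2ccccc12", "drugs"),
    "thiamine": ("Cc1ncc(C[n+]2csc(CCO)c2C)c(N)n1", "endogenites"),
    "riboflavin": (
        "CC1=CC2=C(C=C1C)N(C3=NC(=O)NC(=O)C3=N2)C[C@@H]([C@@H]([C@@H](CO)O)O)O",
        "endogenites",
    ),
    "lumichrome": ("Cc1cc2nc3[nH]c(=O)[nH]c(=O)c3nc2cc1C", "endogenites"),
}


@dataclass(frozen=True)
class PlantedPairSpec:
    """Target overlap counts for a constructed fingerprint pair."""

    a: int
    b: int
    c: int
    length: int = MACCS_NBITS

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c > self.length:
            raise ValueError(
                f"infeasible spec: a+b+c = {self.a + self.b + self.c} "
                f"> length {self.length}"
            )


def construct_pair(
    spec: PlantedPairSpec, seed: int = 0
) -> tuple[Fingerprint, Fingerprint]:
    """Build two fingerprints whose bit_counts equal (a, b, c) exactly.

    Bit positions are placed at random (by seed); only the counts are pinned.
    """
    rng = np.random.default_rng(seed)
    positions = rng.permutation(spec.length)
    only_a = positions[: spec.a]
    only_b = positions[spec.a : spec.a + spec.b]
    shared = positions[spec.a + spec.b : spec.a + spec.b + spec.c]
    A = np.zeros(spec.length, dtype=np.uint8)
    B = np.zeros(spec.length, dtype=np.uint8)
    A[only_a] = 1
    A[shared] = 1
    B[only_b] = 1
    B[shared] = 1
    return Fingerprint(A, "synthetic"), Fingerprint(B, "synthetic")


def random_collection(
    n: int,
    length: int = MACCS_NBITS,
    density: float = 0.3,
    seed: int = 0,
    source_class: str = "synthetic",
    id_prefix: str = "syn",
    mw_range: tuple[float, float] = (100.0, 600.0),
) -> Collection:
    """n independent Bernoulli(density) fingerprints, reproducible by seed.

    Records get ids ``{prefix}0001…`` and molecular weights drawn uniformly
    from ``mw_range`` (synthetic stand-ins, used only by MW matching).
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    matrix = (rng.random((n, length)) < density).astype(np.uint8)
    mws = rng.uniform(*mw_range, size=n)
    records = [
        MoleculeRecord(f"{id_prefix}{i + 1:04d}", "", float(mws[i]), source_class)
        for i in range(n)
    ]
    return Collection(records, matrix, "synthetic")


def worked_example_set() -> Collection:
    """The five embedded molecules with computed MACCS166 fingerprints."""
    pairs = [
        record_from_smiles(smiles, mol_id, cls)
        for mol_id, (smiles, cls) in EMBEDDED_SMILES.items()
    ]
    return Collection.from_pairs(pairs)


def write_smi(path, which: dict[str, tuple[str, str]] | None = None) -> None:
    """Write embedded molecules as a .smi file (SMILES id per line)."""
    which = EMBEDDED_SMILES if which is None else which
    with open(path, "w") as fh:
        fh.write("# embedded worked-example molecules\n")
        for mol_id, (smiles, _) in which.items():
            fh.write(f"{smiles} {mol_id}\n")
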