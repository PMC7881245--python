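"""Small-molecule descriptors for the ligand chemistry.

Fentanyl's flexibility (an elongated 4-anilidopiperidine with seven
rotatable bonds counted by the classical definition, which includes the
amide C-N bond) is part of why it can reorient between binding modes;
this module exposes the few descriptors the analyses refer to.
"""

from __future__ import annotations

FENTANYL_SMILES = "CCC(=O)N(c1ccccc1)C2CCN(CC2)CCc3ccccc3"


def rotatable_bond_count(smiles: str = FENTANYL_SMILES, strict: bool = False) -> int:
    """Number of rotatable bonds of a molecule given as SMILES.

    The default (non-strict) definition counts every acyclic single bond
    between two non-terminal heavy atoms, including amide C-N bonds — the
    classical chemist's count.  ``strict=True`` switches to the pattern that
    excludes amides.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    opt = (rdMolDescriptors.NumRotatableBondsOptions.Strict if strict
           else rdMolDescriptors.NumRotatableBondsOptions.NonStrict)
    return int(rdMolDescriptors.CalcNumRotatableBonds(mol, opt))


def heavy_atom_count(smiles: str = FENTANYL_SMILES) -> int:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    return int(mol.GetNumHeavyAtoms())
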