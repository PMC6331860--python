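"""Optional adapter: Morgan count fingerprints from SMILES via RDKit.

A convenience stand-in for extended-connectivity count fingerprints
(diameter 4 = radius 2), folded to a fixed length.  This module is not part
of the core screening surface — everything else operates on pre-computed
count fingerprints — and RDKit is imported lazily so the package works
without it.
"""

from __future__ import annotations

from pathlib import Path

from .fingerprints import CountFingerprint

__all__ = ["morgan_count_fingerprint", "fingerprints_from_smiles_file"]


def _rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "the SMILES adapter requires rdkit; install it or supply "
            "pre-computed count fingerprints"
        ) from exc
    return Chem, rdFingerprintGenerator


def morgan_count_fingerprint(
    smiles: str, compound_id: str, radius: int = 2, n_bits: int = 1024
) -> CountFingerprint:
    """Folded Morgan count fingerprint of one molecule."""
    Chem, rdFingerprintGenerator = _rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r} for {compound_id!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetCountFingerprint(mol)
    counts = {int(k): int(v) for k, v in fp.GetNonzeroElements().items()}
    return CountFingerprint(compound_id, counts)


def fingerprints_from_smiles_file(
    path, radius: int = 2, n_bits: int = 1024
) -> list[CountFingerprint]:
    """Read ``SMILES[<whitespace>id]`` lines into count fingerprints.

    Lines starting with ``#`` are skipped; a missing id defaults to the
    1-based line number as ``MOL<n>``.
    """
    fps = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"MOL{lineno}"
        fps.append(morgan_count_fingerprint(smiles, cid, radius, n_bits))
    return fps
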