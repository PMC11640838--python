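"""Display-library DNA grammar: flanks, degenerate codon pattern, translation.

A random peptide phage-display library is built from a fixed number of
degenerate codons (NNK by default: any base, any base, G/T) between two
constant flanking sequences. Reads whose variable region violates this
grammar carry sequencing errors and are discarded during curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from Bio.Data.CodonTable import standard_dna_table

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

AMBER = "TAG"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: curation rejection reasons (shared with library_processing)
FLANK_MISMATCH = "flank_mismatch"
CODON_VIOLATION = "codon_violation"
STOP_CODON = "stop_codon"
LOW_QUALITY = "low_quality"


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class PeptideLibraryScheme:
    """DNA grammar of a random-peptide display library.

    Parameters
    ----------
    flank5, flank3
        Constant regions (ACGT only) bracketing the variable region.
    n_codons
        Number of degenerate codons; encoded peptide length.
    codon_pattern
        Three IUPAC letters giving the admissible base class at each codon
        position; the default ``NNK`` encodes all 20 amino acids with a
        single (amber) stop.
    amber_policy
        ``suppress_to_Q``: TAG read through as glutamine (supE host
        convention); ``reject``: TAG treated as any other stop.
    """

    flank5: str = "TCTCACTCTGGTGGTGGT"
    flank3: str = "GGTGGAGGTTCGGGTGCT"
    n_codons: int = 12
    codon_pattern: str = "NNK"
    amber_policy: str = "suppress_to_Q"
    # derived, filled in __post_init__
    _codon_classes: tuple = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        for fl in (self.flank5, self.flank3):
            if set(fl) - set("ACGT"):
                raise ValueError(f"flank contains non-ACGT bases: {fl}")
        if len(self.codon_pattern) != 3:
            raise ValueError("codon_pattern must be 3 IUPAC letters")
        classes = []
        for letter in self.codon_pattern.upper():
            if letter not in IUPAC_CLASSES:
                raise ValueError(f"unknown IUPAC letter {letter!r}")
            classes.append(IUPAC_CLASSES[letter])
        if self.amber_policy not in ("suppress_to_Q", "reject"):
            raise ValueError(f"unknown amber_policy {self.amber_policy!r}")
        object.__setattr__(self, "_codon_classes", tuple(classes))

    # -- geometry ---------------------------------------------------------

    @property
    def variable_length(self) -> int:
        return 3 * self.n_codons

    @property
    def insert_length(self) -> int:
        return len(self.flank5) + self.variable_length + len(self.flank3)

    def variable_region(self, dna: str) -> str:
        return dna[len(self.flank5):len(self.flank5) + self.variable_length]

    # -- codon tables -----------------------------------------------------

    def allowed_codons(self) -> list[str]:
        """All codons admissible under the degenerate pattern."""
        c1, c2, c3 = self._codon_classes
        return [a + b + c for a in c1 for b in c2 for c in c3]

    def translate_codon(self, codon: str) -> Optional[str]:
        """Amino acid for a codon, honouring the amber policy.

        Returns None for a codon that terminates translation (a stop that
        is not suppressed).
        """
        if codon == AMBER:
            return "Q" if self.amber_policy == "suppress_to_Q" else None
        if codon in STOP_CODONS:
            return None
        return standard_dna_table.forward_table[codon]

    def codons_for_aa(self) -> dict[str, list[str]]:
        """Amino acid -> admissible codons under the pattern (stops excluded)."""
        table: dict[str, list[str]] = {}
        for codon in self.allowed_codons():
            aa = self.translate_codon(codon)
            if aa is not None:
                table.setdefault(aa, []).append(codon)
        return table

    # -- validation and translation --------------------------------------

    def validate(self, dna: str) -> Optional[str]:
        """Check a merged read against the library grammar.

        Returns None on pass, otherwise one of the rejection reasons
        (flank_mismatch, codon_violation, stop_codon).
        """
        if len(dna) != self.insert_length:
            # wrong length: cannot locate the variable region reliably
            return FLANK_MISMATCH
        if not dna.startswith(self.flank5) or not dna.endswith(self.flank3):
            return FLANK_MISMATCH
        var = self.variable_region(dna)
        c1, c2, c3 = self._codon_classes
        for i in range(0, len(var), 3):
            codon = var[i:i + 3]
            if codon[0] not in c1 or codon[1] not in c2 or codon[2] not in c3:
                return CODON_VIOLATION
            if codon in STOP_CODONS and not (
                codon == AMBER and self.amber_policy == "suppress_to_Q"
            ):
                return STOP_CODON
        return None

    def translate(self, dna: str) -> str:
        """Translate a validated insert's variable region to peptide."""
        var = self.variable_region(dna)
        aas = []
        for i in range(0, len(var), 3):
            aa = self.translate_codon(var[i:i + 3])
            if aa is None:
                raise ValueError(f"stop codon {var[i:i+3]} in variable region")
            aas.append(aa)
        return "".join(aas)

    def encode_peptide(self, peptide: str, rng: np.random.Generator) -> str:
        """Reverse-translate a peptide into one admissible insert DNA.

        Codons are drawn uniformly from the admissible codons for each
        residue; raises if a residue has no codon under the pattern.
        """
        if len(peptide) != self.n_codons:
            raise ValueError(
                f"peptide length {len(peptide)} != n_codons {self.n_codons}"
            )
        table = self.codons_for_aa()
        codons = []
        for aa in peptide:
            choices = table.get(aa)
            if not choices:
                raise ValueError(
                    f"residue {aa!r} not encodable under pattern {self.codon_pattern}"
                )
            codons.append(choices[rng.integers(len(choices))])
        return self.flank5 + "".join(codons) + self.flank3

    def random_variable_dna(self, rng: np.random.Generator) -> str:
        """One random variable region (codons uniform over the pattern)."""
        codons = self.allowed_codons()
        idx = rng.integers(len(codons), size=self.n_codons)
        return "".join(codons[i] for i in idx)

    # -- config I/O -------------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "flank5": self.flank5,
                "flank3": self.flank3,
                "n_codons": self.n_codons,
                "codon_pattern": self.codon_pattern,
                "amber_policy": self.amber_policy,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PeptideLibraryScheme":
        return cls(**yaml.safe_load(text))


DEFAULT_SCHEME = PeptideLibraryScheme()
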