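"""Synthetic proteome samples: digestion, m/z, retention, mixtures.

This module generates every input the simulator needs without external
downloads: seeded synthetic protein databases, tryptic digests, peptide
physicochemistry (monoisotopic m/z with fixed carbamidomethyl-C, additive
hydrophobicity retention), log-normal protein abundances spanning a >6-log
dynamic range, three-species mixture designs (E5H50Y45 ... E45H50Y5),
shuffled/foreign entrapment databases for empirical FDR work, and offline
high-pH fractionation / concatenation maps.

Everything keyed off a peptide sequence (charge state, ionization response,
retention jitter) is a deterministic hash of that sequence, so the same
peptide behaves identically across runs and mixture designs — the property
the species-mixture benchmark relies on.
"""

from __future__ import annotations

import hashlib
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParamData import kd as _KD_HYDROPHOBICITY
from pyteomics import mass as _pmass
from pyteomics import parser as _pparser
from scipy import stats as _stats

PROTON_MASS = 1.00727646677
CARBAMIDOMETHYL_MASS = 57.02146

#: Monoisotopic residue masses with fixed carbamidomethylation on cysteine.
AA_MASS: dict[str, float] = dict(_pmass.std_aa_mass)
AA_MASS["C"] = AA_MASS["C"] + CARBAMIDOMETHYL_MASS

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Trypsin specificity (LysC termini are a subset): cleave C-terminal to
#: K/R unless the next residue is proline.
TRYPSIN_RULE = r"(?<=[KR])(?!P)"

#: Average residue frequencies of a vertebrate proteome, used by the
#: synthetic database generator.
_RESIDUE_FREQS = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}

SPECIES_CODES = {"E": "ecoli", "H": "human", "Y": "yeast"}


class DigestionError(ValueError):
    """Raised for sequences the protease model cannot handle."""


@dataclass
class ProteinEntry:
    """One database entry: accession, species label, sequence, abundance.

    ``base_abundance`` is an arbitrary copy-number unit (ion flux budget in
    charges/s once propagated to peptides); NaN until assigned.
    """

    accession: str
    species: str
    sequence: str
    base_abundance: float = math.nan


@dataclass(frozen=True)
class PeptideIon:
    """A charged, digested peptide species ready for acquisition.

    ``abundance`` is the apex ion flux in charges/s delivered to the
    instrument; the chromatographic profile is Gaussian with the given FWHM
    centered on ``rt_apex``.
    """

    sequence: str
    protein_accessions: tuple[str, ...]
    species: str
    charge: int
    mz: float
    rt_apex: float
    peak_fwhm: float
    abundance: float
    missed_cleavages: int = 0

    @property
    def precursor_id(self) -> str:
        return f"{self.sequence}/{self.charge}"


@dataclass(frozen=True)
class MixtureDesign:
    """Species-mixture composition, e.g. E5H50Y45 -> {ecoli 5, human 50, yeast 45}."""

    label: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(
                f"mixture {self.label!r} percentages sum to {total}, not 100"
            )

    @classmethod
    def parse(cls, label: str) -> "MixtureDesign":
        """Parse compact labels such as ``"E45H50Y5"`` or ``"H100"``."""
        parts = re.findall(r"([A-Z])(\d+(?:\.\d+)?)", label)
        if not parts or "".join(c + n for c, n in parts) != label:
            raise ValueError(f"cannot parse mixture label {label!r}")
        fractions = {}
        for code, pct in parts:
            species = SPECIES_CODES.get(code, code.lower())
            fractions[species] = float(pct)
        return cls(label=label, fractions=fractions)

    def expected_log2(self, other: "MixtureDesign", species: str) -> float:
        """Expected log2 ratio self/other for one species."""
        return math.log2(self.fractions[species] / other.fractions[species])


#: The six benchmark designs (human held at 50% throughout).
SIX_DESIGN_LABELS = (
    "E5H50Y45", "E10H50Y40", "E20H50Y30",
    "E30H50Y20", "E40H50Y10", "E45H50Y5",
)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise DigestionError("empty protein sequence")
    bad = set(sequence) - set(CANONICAL_RESIDUES)
    if bad:
        raise DigestionError(f"non-canonical residues {sorted(bad)}")


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    min_length: Optional[int] = None,
    max_length: Optional[int] = None,
) -> set[str]:
    """Tryptic digest of one sequence.

    Cleaves C-terminal to K or R, never before P, emitting all products
    with 0..``missed_cleavages`` internal sites.  Optional length bounds
    implement the detectable-peptide filter (applied downstream by
    `digest_proteome`, 7–30 residues by default there).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    _check_sequence(sequence)
    peptides = _pparser.cleave(sequence, TRYPSIN_RULE, missed_cleavages)
    if min_length is not None:
        peptides = {p for p in peptides if len(p) >= min_length}
    if max_length is not None:
        peptides = {p for p in peptides if len(p) <= max_length}
    return set(peptides)


def count_missed_cleavages(peptide: str) -> int:
    """Internal (uncleaved) tryptic sites within a peptide."""
    return sum(
        1
        for i in range(len(peptide) - 1)
        if peptide[i] in "KR" and peptide[i + 1] != "P"
    )


def peptide_mz(sequence: str, charge: int) -> float:
    """Monoisotopic m/z: (residue masses + water + charge protons) / charge.

    Cysteines carry fixed carbamidomethylation (+57.02146 Da).
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    _check_sequence(sequence)
    return _pmass.fast_mass(sequence, charge=charge, aa_mass=AA_MASS)


def fragment_mzs(sequence: str) -> np.ndarray:
    """Sorted singly charged b/y fragment m/z values (no neutral losses)."""
    _check_sequence(sequence)
    frags = []
    for i in range(1, len(sequence)):
        frags.append(
            _pmass.fast_mass(sequence[:i], ion_type="b", charge=1, aa_mass=AA_MASS)
        )
        frags.append(
            _pmass.fast_mass(sequence[i:], ion_type="y", charge=1, aa_mass=AA_MASS)
        )
    return np.sort(np.asarray(frags))


def _stable_uniform(key: str, salt: str) -> float:
    """Deterministic uniform(0, 1) from a string, independent of any RNG."""
    digest_ = hashlib.md5(f"{salt}:{key}".encode()).digest()
    return int.from_bytes(digest_[:8], "big") / 2**64


def hydrophobicity(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy of a sequence."""
    return sum(_KD_HYDROPHOBICITY[a] for a in sequence) / len(sequence)


def predict_rt(
    sequence: str, gradient_length_s: float, jitter: float = 0.06
) -> float:
    """Retention-time apex from an additive hydrophobicity index.

    The mean Kyte–Doolittle hydropathy (range −4.5..4.5) is mapped linearly
    onto the gradient; a small sequence-keyed jitter models orthogonal
    retention effects so compositionally similar peptides do not co-elute
    perfectly.  Deterministic: identical sequences always get identical
    retention times, and the result always lies within [0, gradient].
    """
    if gradient_length_s <= 0:
        raise ValueError("gradient length must be > 0")
    _check_sequence(sequence)
    base = (hydrophobicity(sequence) + 4.5) / 9.0
    wobble = (_stable_uniform(sequence, "rt") - 0.5) * jitter
    return float(np.clip(base + wobble, 0.0, 1.0)) * gradient_length_s


def generate_proteome(
    n_proteins: int,
    species: str,
    seed: int,
    length_range: tuple[int, int] = (150, 600),
    accession_prefix: Optional[str] = None,
) -> list[ProteinEntry]:
    """Seeded synthetic protein database with realistic residue frequencies."""
    rng = np.random.default_rng([seed, _species_salt(species)])
    residues = np.array(list(_RESIDUE_FREQS))
    probs = np.array(list(_RESIDUE_FREQS.values()))
    probs = probs / probs.sum()
    prefix = accession_prefix or species[:3].upper()
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        proteins.append(
            ProteinEntry(
                accession=f"{prefix}{i:05d}", species=species, sequence=seq
            )
        )
    return proteins


def _species_salt(species: str) -> int:
    return int.from_bytes(hashlib.md5(species.encode()).digest()[:4], "big")


def assign_abundances(
    proteins: Sequence[ProteinEntry],
    dynamic_range_logs: float = 6.0,
    seed: int = 0,
    median_log10: float = 4.0,
) -> list[ProteinEntry]:
    """Draw log-normal protein abundances spanning a wide dynamic range.

    log10 abundances are normal with a spread chosen so the 1st–99th
    percentile span comfortably exceeds ``dynamic_range_logs`` (a 15%
    margin over the exact quantile arithmetic keeps the empirical span
    above the target at finite n).  Deterministic under ``seed``.
    """
    z99 = _stats.norm.ppf(0.99)
    sigma = 1.15 * dynamic_range_logs / (2.0 * z99)
    rng = np.random.default_rng([seed, 0xAB])
    out = []
    for p in proteins:
        log10_a = median_log10 + sigma * rng.standard_normal()
        out.append(replace_protein(p, base_abundance=10.0**log10_a))
    return out


def replace_protein(p: ProteinEntry, **kw) -> ProteinEntry:
    d = dict(
        accession=p.accession,
        species=p.species,
        sequence=p.sequence,
        base_abundance=p.base_abundance,
    )
    d.update(kw)
    return ProteinEntry(**d)


def digest_proteome(
    proteins: Sequence[ProteinEntry],
    gradient_length_s: float,
    missed_cleavages: int = 0,
    min_length: int = 7,
    max_length: int = 30,
    peak_fwhm_s: float = 6.0,
    charge_probs: Mapping[int, float] = None,
    ionization_sigma_log10: float = 0.5,
) -> list[PeptideIon]:
    """Digest a database into detectable peptide ions.

    Applies the 7–30 residue length filter, drops peptides shared between
    accessions (proteotypic-only quantification), assigns one charge state
    per sequence from ``charge_probs`` (default 2+:0.7, 3+:0.3) and a
    log-normal per-sequence ionization response — both as deterministic
    hashes of the sequence.  Peptide apex flux = protein abundance ×
    response factor.
    """
    if charge_probs is None:
        charge_probs = {2: 0.7, 3: 0.3}
    seq_owner: dict[str, list[ProteinEntry]] = {}
    seq_mc: dict[str, int] = {}
    for protein in proteins:
        for pep in digest(
            protein.sequence, missed_cleavages, min_length, max_length
        ):
            seq_owner.setdefault(pep, []).append(protein)
            seq_mc[pep] = count_missed_cleavages(pep)

    charges = sorted(charge_probs)
    cum = np.cumsum([charge_probs[z] for z in charges])
    cum = cum / cum[-1]

    ions = []
    for pep, owners in sorted(seq_owner.items()):
        if len({o.accession for o in owners}) > 1:
            continue  # non-proteotypic
        protein = owners[0]
        if not np.isfinite(protein.base_abundance):
            raise ValueError(
                f"protein {protein.accession} has no abundance assigned"
            )
        u = _stable_uniform(pep, "charge")
        charge = charges[int(np.searchsorted(cum, u, side="right"))]
        u_resp = min(max(_stable_uniform(pep, "response"), 1e-12), 1 - 1e-12)
        response = 10.0 ** (ionization_sigma_log10 * _stats.norm.ppf(u_resp))
        ions.append(
            PeptideIon(
                sequence=pep,
                protein_accessions=(protein.accession,),
                species=protein.species,
                charge=charge,
                mz=peptide_mz(pep, charge),
                rt_apex=predict_rt(pep, gradient_length_s),
                peak_fwhm=peak_fwhm_s,
                abundance=protein.base_abundance * response,
                missed_cleavages=seq_mc[pep],
            )
        )
    return ions


def make_mixture(
    digests: Mapping[str, Sequence[PeptideIon]],
    design: MixtureDesign,
    load_factor: float = 1.0,
) -> list[PeptideIon]:
    """Combine per-species digests according to a mixture design.

    Each species' peptide fluxes are scaled by its percentage / 100 (times
    a global ``load_factor`` modeling column load), so e.g. every E. coli
    peptide is exactly 9× more abundant in E45H50Y5 than in E5H50Y45 while
    human peptides are identical across all six designs.
    """
    mixed = []
    for species, fraction in design.fractions.items():
        if species not in digests:
            raise KeyError(f"no digest provided for species {species!r}")
        scale = fraction / 100.0 * load_factor
        for ion in digests[species]:
            mixed.append(replace(ion, abundance=ion.abundance * scale))
    return mixed


def make_entrapment_db(
    proteins: Sequence[ProteinEntry],
    ratio: int,
    mode: str = "shuffled",
    seed: int = 0,
) -> list[ProteinEntry]:
    """Build an entrapment database ``ratio``× the size of the target.

    ``shuffled`` permutes every target sequence (length and residue
    composition preserved, K/R positions re-drawn with the rest), emitting
    ``ratio`` mimic entries per target and guaranteeing no mimic equals its
    source for length > 3.  ``foreign`` synthesizes length-matched
    sequences from a perturbed residue-frequency profile, mimicking a
    search against an unrelated organism.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if mode not in ("shuffled", "foreign"):
        raise ValueError(f"unknown entrapment mode {mode!r}")
    rng = np.random.default_rng([seed, 0xE7])
    entries: list[ProteinEntry] = []
    if mode == "foreign":
        freqs = dict(_RESIDUE_FREQS)
        # tilt the composition so foreign sequences are statistically distinct
        for r, mult in (("A", 1.5), ("S", 1.4), ("L", 0.6), ("K", 1.2)):
            freqs[r] *= mult
        residues = np.array(list(freqs))
        probs = np.array(list(freqs.values()))
        probs = probs / probs.sum()
    for k in range(ratio):
        for p in proteins:
            if mode == "shuffled":
                seq_arr = np.array(list(p.sequence))
                mimic = "".join(rng.permutation(seq_arr))
                while len(p.sequence) > 3 and mimic == p.sequence:
                    mimic = "".join(rng.permutation(seq_arr))
            else:
                mimic = "".join(
                    rng.choice(residues, size=len(p.sequence), p=probs)
                )
            entries.append(
                ProteinEntry(
                    accession=f"ENTRAP{k}_{p.accession}",
                    species="entrapment",
                    sequence=mimic,
                    base_abundance=p.base_abundance,
                )
            )
    return entries


def is_entrapment_accession(accession: str) -> bool:
    return accession.startswith("ENTRAP")


def fractionate(
    peptides: Sequence[PeptideIon], n_fractions: int = 46
) -> np.ndarray:
    """Assign peptides to offline first-dimension fractions.

    Quantile binning on the first-dimension hydrophobicity score: fraction
    sizes differ by at most one and elution order is preserved across
    fraction boundaries.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    scores = np.array([hydrophobicity(p.sequence) for p in peptides])
    order = np.argsort(scores, kind="stable")
    assignment = np.empty(len(peptides), dtype=int)
    for frac_idx, chunk in enumerate(np.array_split(order, n_fractions)):
        assignment[chunk] = frac_idx
    return assignment


def concatenation_map(n_fractions: int = 46, n_pools: int = 12) -> dict[int, int]:
    """Round-robin concatenation of offline fractions into pools.

    Fraction ``i`` goes to pool ``i mod n_pools`` (e.g. 46 fractions into 23
    pools sends fractions 0 and 23 to pool 0), so each pool mixes distant,
    dissimilar fractions — the standard concatenation strategy.
    """
    if not 1 <= n_pools <= n_fractions:
        raise ValueError("need 1 <= n_pools <= n_fractions")
    return {i: i % n_pools for i in range(n_fractions)}


def sequence_coverage(
    protein: ProteinEntry, identified_peptides: Iterable[str]
) -> float:
    """Percentage of protein residues covered by identified peptides.

    All occurrences of every peptide are located in the protein sequence
    and the union of the spans (overlaps merged, counted once) is divided
    by the protein length.
    """
    seq = protein.sequence
    intervals: list[tuple[int, int]] = []
    for pep in identified_peptides:
        start = seq.find(pep)
        while start != -1:
            intervals.append((start, start + len(pep)))
            start = seq.find(pep, start + 1)
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return 100.0 * covered / len(seq)


def write_fasta(proteins: Sequence[ProteinEntry], path) -> None:
    """Write a FASTA database (accession as first header token, species tag)."""
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.accession,
            description=f"species={p.species}",
        )
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, species_tag: str = "species") -> list[ProteinEntry]:
    """Read a FASTA database; species parsed from a ``tag=value`` header field."""
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = "unknown"
        for token in rec.description.split():
            if token.startswith(f"{species_tag}="):
                species = token.split("=", 1)[1]
        proteins.append(
            ProteinEntry(
                accession=rec.id, species=species, sequence=str(rec.seq)
            )
        )
    if not proteins:
        warnings.warn(f"no sequences found in {path}")
    return proteins
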