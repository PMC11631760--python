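"""Digestion, peptide physicochemistry, mixtures and entrapment databases."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ndiasim.sample import (
    DigestionError,
    MixtureDesign,
    ProteinEntry,
    SIX_DESIGN_LABELS,
    assign_abundances,
    concatenation_map,
    count_missed_cleavages,
    digest,
    digest_proteome,
    fractionate,
    fragment_mzs,
    generate_proteome,
    hydrophobicity,
    make_entrapment_db,
    make_mixture,
    peptide_mz,
    predict_rt,
    read_fasta,
    sequence_coverage,
    write_fasta,
)

PROTON = 1.00727646677
WATER = 18.0105646863

#: Independent monoisotopic residue masses (literature values), cysteine
#: fixed-carbamidomethylated.  Deliberately not imported from the package.
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185 + 57.02146,
    "L": 113.084064, "I": 113.084064, "N": 114.042927, "D": 115.026943,
    "Q": 128.058578, "K": 128.094963, "E": 129.042593, "M": 131.040485,
    "H": 137.058912, "F": 147.068414, "R": 156.101111, "Y": 163.063329,
    "W": 186.079313,
}

AA = st.sampled_from(sorted(RESIDUE_MASS))
SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=50)


def oracle_digest(seq: str, missed: int) -> set[str]:
    """Brute-force tryptic digest: enumerate fragments between cleavage sites."""
    sites = [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]
    bounds = [0] + sites + [len(seq)]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + missed, len(bounds))):
            out.add(seq[bounds[a]:bounds[b]])
    return out


def test_digest_examples():
    assert digest("MKAYRPEPKR", 0) == {"MK", "AYRPEPK", "R"}
    assert digest("ACDEFG", 0) == {"ACDEFG"}  # no cleavage sites
    assert digest("AKAKA", 1) == oracle_digest("AKAKA", 1)


def test_digest_rejects_bad_input():
    with pytest.raises(DigestionError):
        digest("", 0)
    with pytest.raises(DigestionError):
        digest("PEPTIDEX", 0)
    with pytest.raises(ValueError):
        digest("PEPTIDE", -1)


@given(seq=SEQ, missed=st.integers(0, 2))
def test_digest_matches_bruteforce_enumeration(seq, missed):
    assert digest(seq, missed) == oracle_digest(seq, missed)


def test_missed_cleavage_counter():
    assert count_missed_cleavages("AYRPEPK") == 0  # RP does not cleave
    assert count_missed_cleavages("AKAK") == 1
    assert count_missed_cleavages("AKRK") == 2


def test_peptide_mz_reference_value():
    # PEPTIDE 2+: monoisotopic mass 799.3600 Da
    assert peptide_mz("PEPTIDE", 2) == pytest.approx(400.6872, abs=1e-3)


def test_cysteine_carries_carbamidomethylation():
    expected = (RESIDUE_MASS["C"] + WATER + PROTON) / 1.0
    assert peptide_mz("C", 1) == pytest.approx(expected, abs=1e-4)


@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
def test_peptide_mz_matches_independent_residue_table(seq):
    for charge in (1, 2, 3):
        expected = (
            sum(RESIDUE_MASS[a] for a in seq) + WATER + charge * PROTON
        ) / charge
        assert peptide_mz(seq, charge) == pytest.approx(expected, abs=1e-4)


@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
def test_charge_states_obey_proton_identity(seq):
    mz1 = peptide_mz(seq, 1)
    mz2 = peptide_mz(seq, 2)
    assert mz1 == pytest.approx(2.0 * mz2 - PROTON, abs=1e-6)


def test_fragment_mzs_are_sorted_by_and_y_pairs():
    frags = fragment_mzs("PEPTIDE")
    assert len(frags) == 2 * (len("PEPTIDE") - 1)
    assert np.all(np.diff(frags) >= 0)
    # y1 of ...E = E residue + water + proton
    y1 = RESIDUE_MASS["E"] + WATER + PROTON
    assert np.min(np.abs(frags - y1)) < 1e-4


def test_retention_prediction_orders_by_hydrophobicity():
    assert predict_rt("KKKK", 1000.0) < predict_rt("LLLL", 1000.0)
    assert predict_rt("AAAA", 1000.0) == predict_rt("AAAA", 1000.0)
    with pytest.raises(ValueError):
        predict_rt("PEPTIDE", 0.0)


@given(seq=SEQ, gradient=st.floats(1.0, 1e5))
def test_retention_times_stay_on_the_gradient(seq, gradient):
    rt = predict_rt(seq, gradient)
    assert 0.0 <= rt <= gradient


def test_abundance_generator_spans_dynamic_range():
    proteins = [
        ProteinEntry(f"P{i}", "human", "PEPTIDEK") for i in range(10_000)
    ]
    out = assign_abundances(proteins, dynamic_range_logs=6.0, seed=5)
    logs = np.log10([p.base_abundance for p in out])
    assert np.percentile(logs, 99) - np.percentile(logs, 1) >= 6.0
    # reproducible under the same seed
    again = assign_abundances(proteins, dynamic_range_logs=6.0, seed=5)
    assert [p.base_abundance for p in again] == [p.base_abundance for p in out]


def test_zero_dynamic_range_collapses_to_equal_abundance():
    proteins = [ProteinEntry(f"P{i}", "human", "AAAK") for i in range(50)]
    out = assign_abundances(proteins, dynamic_range_logs=0.0, seed=1)
    vals = {p.base_abundance for p in out}
    assert len(vals) == 1


def test_digest_proteome_is_proteotypic_and_annotated():
    proteins = assign_abundances(
        generate_proteome(10, "yeast", seed=2), seed=2
    )
    ions = digest_proteome(proteins, gradient_length_s=600.0)
    assert ions
    seqs = [i.sequence for i in ions]
    assert len(seqs) == len(set(seqs))  # shared peptides dropped
    for ion in ions:
        assert 7 <= len(ion.sequence) <= 30
        assert ion.charge in (2, 3)
        assert ion.abundance > 0
        assert 0.0 <= ion.rt_apex <= 600.0
        assert ion.mz == pytest.approx(
            peptide_mz(ion.sequence, ion.charge), abs=1e-9
        )


@pytest.fixture(scope="module")
def species_digests():
    digests = {}
    for sp in ("human", "yeast", "ecoli"):
        prots = assign_abundances(generate_proteome(8, sp, seed=4), seed=4)
        digests[sp] = digest_proteome(prots, gradient_length_s=600.0)
    return digests


def test_mixture_scaling_ratios(species_digests):
    e45 = make_mixture(species_digests, MixtureDesign.parse("E45H50Y5"))
    e5 = make_mixture(species_digests, MixtureDesign.parse("E5H50Y45"))
    a45 = {p.precursor_id: p.abundance for p in e45 if p.species == "ecoli"}
    a5 = {p.precursor_id: p.abundance for p in e5 if p.species == "ecoli"}
    for pid in a45:
        assert a45[pid] / a5[pid] == pytest.approx(9.0, rel=1e-12)
    h45 = {p.precursor_id: p.abundance for p in e45 if p.species == "human"}
    h5 = {p.precursor_id: p.abundance for p in e5 if p.species == "human"}
    for pid in h45:
        assert h45[pid] == pytest.approx(h5[pid], rel=1e-12)
    y20 = make_mixture(species_digests, MixtureDesign.parse("E30H50Y20"))
    y30 = make_mixture(species_digests, MixtureDesign.parse("E20H50Y30"))
    b20 = {p.precursor_id: p.abundance for p in y20 if p.species == "yeast"}
    b30 = {p.precursor_id: p.abundance for p in y30 if p.species == "yeast"}
    for pid in b20:
        assert b20[pid] / b30[pid] == pytest.approx(2.0 / 3.0, rel=1e-12)


def test_human_background_conserved_across_all_six_designs(species_digests):
    totals = []
    for label in SIX_DESIGN_LABELS:
        mixed = make_mixture(species_digests, MixtureDesign.parse(label))
        totals.append(
            sum(p.abundance for p in mixed if p.species == "human")
        )
    for t in totals[1:]:
        assert t == pytest.approx(totals[0], rel=1e-9)


def test_mixture_design_parsing_and_validation():
    d = MixtureDesign.parse("E5H50Y45")
    assert d.fractions == {"ecoli": 5.0, "human": 50.0, "yeast": 45.0}
    assert d.expected_log2(MixtureDesign.parse("E45H50Y5"), "human") == 0.0
    with pytest.raises(ValueError):
        MixtureDesign.parse("E5H50Y40")  # sums to 95
    with pytest.raises(ValueError):
        MixtureDesign.parse("banana")


def test_entrapment_database_shuffled_mode():
    proteins = generate_proteome(15, "human", seed=6)
    mimics = make_entrapment_db(proteins, ratio=9, mode="shuffled", seed=6)
    assert len(mimics) == 9 * len(proteins)
    for k, mimic in enumerate(mimics):
        source = proteins[k % len(proteins)]
        assert mimic.species == "entrapment"
        assert mimic.accession.startswith("ENTRAP")
        assert Counter(mimic.sequence) == Counter(source.sequence)
        assert mimic.sequence != source.sequence  # length > 3 guaranteed here
    assert make_entrapment_db(proteins, ratio=0) == []


def test_entrapment_database_foreign_mode():
    proteins = generate_proteome(5, "human", seed=6)
    foreign = make_entrapment_db(proteins, ratio=2, mode="foreign", seed=6)
    assert len(foreign) == 2 * len(proteins)
    for k, entry in enumerate(foreign):
        assert len(entry.sequence) == len(proteins[k % len(proteins)].sequence)


def test_fractionation_is_balanced_and_ordered(species_digests):
    peptides = species_digests["human"]
    assignment = fractionate(peptides, n_fractions=7)
    counts = Counter(assignment)
    assert max(counts.values()) - min(counts.values()) <= 1
    scores = np.array([hydrophobicity(p.sequence) for p in peptides])
    for f in range(6):
        assert scores[assignment == f].max() <= scores[
            assignment == f + 1
        ].min() + 1e-12
    assert set(fractionate(peptides, n_fractions=1)) == {0}


def test_concatenation_map_round_robin():
    cmap = concatenation_map(46, 23)
    assert cmap[0] == cmap[23] == 0
    assert concatenation_map(46, 46) == {i: i for i in range(46)}
    sizes = Counter(concatenation_map(46, 12).values())
    assert max(sizes.values()) - min(sizes.values()) <= 1


def test_sequence_coverage_merges_overlaps():
    protein = ProteinEntry("P1", "human", "MKAYRPEPKRSTVVV")
    assert sequence_coverage(protein, [protein.sequence]) == 100.0
    halves = [protein.sequence[:7], protein.sequence[7:]]
    assert sequence_coverage(protein, halves) == 100.0
    assert sequence_coverage(protein, []) == 0.0
    # overlapping peptides counted once: interval-merge oracle
    peptides = ["MKAYR", "AYRPEP", "STV"]
    covered = set()
    for pep in peptides:
        start = protein.sequence.find(pep)
        while start != -1:
            covered.update(range(start, start + len(pep)))
            start = protein.sequence.find(pep, start + 1)
    expected = 100.0 * len(covered) / len(protein.sequence)
    assert sequence_coverage(protein, peptides) == pytest.approx(expected)


def test_fasta_round_trip(tmp_path):
    proteins = generate_proteome(6, "ecoli", seed=9)
    path = tmp_path / "db.fasta"
    write_fasta(proteins, path)
    back = read_fasta(path)
    assert [(p.accession, p.species, p.sequence) for p in back] == [
        (p.accession, p.species, p.sequence) for p in proteins
    ]
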