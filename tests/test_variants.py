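import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtphylogeo.reference import MT_LENGTH, transition_partner
from mtphylogeo.variants import (
    CONTROL,
    DELETION,
    INDEL,
    INSERTION,
    FULL_COVERAGE,
    Mutation,
    MutationError,
    NONCODING,
    NONSYNONYMOUS,
    RRNA,
    SYNONYMOUS,
    TRANSITION,
    TRANSVERSION,
    TRNA,
    VariantProfile,
    apply_exclusion_filter,
    call_variants,
    classify_mutation_function,
    format_mutation,
    format_mutations,
    mutate_sequence,
    parse_mutation_token,
    parse_tokens,
    read_variant_table,
    write_variant_table,
)


# --- token parsing --------------------------------------------------------


def test_parse_insertion(reference):
    (m,) = parse_mutation_token("16193.1C", reference)
    assert m.kind == INSERTION
    assert m.position == 16193
    assert m.insertion_index == 1
    assert m.derived == "C"


def test_parse_ranged_deletion(reference):
    muts = parse_mutation_token("8281-8289d", reference)
    assert len(muts) == 9
    assert [m.position for m in muts] == list(range(8281, 8290))
    assert all(m.kind == DELETION for m in muts)


def test_parse_bare_transition(reference):
    (m,) = parse_mutation_token("16172", reference)
    assert m.kind == TRANSITION
    assert m.ref == reference.base_at(16172)
    assert m.derived == transition_partner(reference.base_at(16172))


def test_parse_transversion_suffix(reference):
    # 16183 is pinned to A in the bundled reference, so "16183C" is A->C
    (m,) = parse_mutation_token("16183C", reference)
    assert m.kind == TRANSVERSION
    assert m.derived == "C"


def test_parse_back_mutation(reference):
    (m,) = parse_mutation_token("@10398", reference)
    assert m.back_mutation
    assert m.derived == reference.base_at(10398)


def test_parse_plus_insertion_normalized(reference):
    muts = parse_mutation_token("573+CC", reference)
    assert [(-1) if m.kind != INSERTION else m.insertion_index for m in muts] == [1, 2]
    assert all(m.derived == "C" for m in muts)


def test_parse_leading_refbase_validated(reference):
    refbase = reference.base_at(73)
    (m,) = parse_mutation_token(f"{refbase}73{transition_partner(refbase)}", reference)
    assert m.position == 73
    wrong = "C" if refbase != "C" else "G"
    with pytest.raises(MutationError):
        parse_mutation_token(f"{wrong}73T", reference)


@pytest.mark.parametrize("token", ["0", "16570", "99999", "abc", "12.C", "12..1C", ""])
def test_parse_malformed(token, reference):
    with pytest.raises(MutationError):
        parse_mutation_token(token, reference)


def test_parse_derived_equals_reference_rejected(reference):
    refbase = reference.base_at(5000)
    with pytest.raises(MutationError):
        parse_mutation_token(f"5000{refbase}", reference)


# --- formatting round trip -------------------------------------------------


def test_format_examples(reference):
    (m,) = parse_mutation_token("16172", reference)
    assert format_mutation(m) == "16172"
    (m,) = parse_mutation_token("16183C", reference)
    assert format_mutation(m) == "16183C"
    (m,) = parse_mutation_token("@10398", reference)
    assert format_mutation(m) == "@10398"


def test_format_compacts_deletion_runs(reference):
    muts = parse_mutation_token("8281-8289d", reference)
    assert format_mutations(muts) == ["8281-8289d"]


@settings(max_examples=200, deadline=None)
@given(
    position=st.integers(min_value=1, max_value=MT_LENGTH),
    style=st.sampled_from(["transition", "transversion", "insertion", "deletion", "back"]),
    base=st.sampled_from("ACGT"),
    idx=st.integers(min_value=1, max_value=3),
)
def test_parse_format_round_trip(position, style, base, idx, reference):
    refbase = reference.base_at(position)
    if style == "transition":
        token = str(position)
    elif style == "transversion":
        if base == refbase or base == transition_partner(refbase):
            token = str(position)
        else:
            token = f"{position}{base}"
    elif style == "insertion":
        token = f"{position}.{idx}{base}"
    elif style == "deletion":
        token = f"{position}d"
    else:
        token = f"@{position}"
    muts = parse_mutation_token(token, reference)
    assert len(muts) == 1
    assert parse_mutation_token(format_mutation(muts[0]), reference) == muts


# --- profiles -------------------------------------------------------------


def test_profile_requires_coverage(reference):
    m = parse_mutation_token("16189", reference)
    with pytest.raises(ValueError):
        VariantProfile("s", [(100, 200)], m)


def test_profile_rejects_duplicates(reference):
    m = parse_mutation_token("16189", reference)[0]
    with pytest.raises(ValueError):
        VariantProfile("s", FULL_COVERAGE, [m, m])


def test_profile_wrap_coverage(reference):
    p = VariantProfile("s", [(16024, 407)], parse_tokens("16189 73", reference))
    assert p.covers(16500) and p.covers(100) and not p.covers(8000)


# --- variant calling ------------------------------------------------------


def test_call_variants_identity(reference):
    seq = "".join(reference.base_at(p) for p in range(16024, 16570))
    seq += "".join(reference.base_at(p) for p in range(1, 408))
    prof = call_variants(seq, [(16024, 407)], reference)
    assert prof.mutations == []


def test_call_variants_single_transition(reference):
    covered = [(16024, 407)]
    muts = parse_mutation_token("16189", reference)
    full = mutate_sequence(reference, muts)
    seq = full[16023:16569] + full[0:407]
    prof = call_variants(seq, covered, reference)
    assert [format_mutation(m) for m in prof.mutations] == ["16189"]


def test_call_variants_nine_bp_deletion_three_prime_placement(reference):
    # removing one copy of the tandem 9-bp repeat must report 8281-8289d
    full = list(reference.bases)
    del full[8280:8289]
    prof = call_variants("".join(full), list(FULL_COVERAGE), reference)
    assert format_mutations(prof.mutations) == ["8281-8289d"]


def test_call_variants_ambiguity_uncovers_position(reference):
    seq = list(reference.bases)
    seq[999] = "N"
    prof = call_variants("".join(seq), list(FULL_COVERAGE), reference)
    assert prof.mutations == []
    assert not prof.covers(1000)
    assert prof.covers(999) and prof.covers(1001)


def test_call_variants_rejects_bad_characters(reference):
    with pytest.raises(ValueError):
        call_variants("AXGT", [(1, 4)], reference)
    with pytest.raises(ValueError):
        call_variants("ACGT", [], reference)


def test_call_variants_fuzz_substitutions(reference):
    import numpy as np

    rng = np.random.default_rng(42)
    excluded = set(range(303, 316)) | set(range(515, 523)) | {16182, 16183, 16193, 16519}
    for _ in range(10):
        k = rng.integers(1, 12)
        positions = set()
        while len(positions) < k:
            p = int(rng.integers(1, MT_LENGTH + 1))
            if p not in excluded:
                positions.add(p)
        muts = [parse_mutation_token(str(p), reference)[0] for p in sorted(positions)]
        seq = mutate_sequence(reference, muts)
        prof = call_variants(seq, list(FULL_COVERAGE), reference)
        assert sorted(m.key for m in prof.mutations) == sorted(m.key for m in muts)


# --- functional classification --------------------------------------------


def test_classify_trna(reference):
    f = next(x for x in reference.features if x.name == "TF")
    m = parse_mutation_token(str(f.start + 5), reference)[0]
    assert classify_mutation_function(m, reference) == TRNA


def test_classify_rrna(reference):
    m = parse_mutation_token("1000", reference)[0]  # 12S rRNA
    assert classify_mutation_function(m, reference) == RRNA


def test_classify_intergenic_noncoding(reference):
    m = parse_mutation_token("5582", reference)[0]  # between TW and TA
    assert not reference.features_at(5582)
    assert classify_mutation_function(m, reference) == NONCODING


def test_classify_control_region(reference):
    m = parse_mutation_token("16189", reference)[0]
    assert classify_mutation_function(m, reference) == CONTROL


def test_classify_indel_marker(reference):
    m = parse_mutation_token("8281d", reference)[0]
    assert classify_mutation_function(m, reference) == INDEL
    (ins,) = parse_mutation_token("5740.1A", reference)
    assert classify_mutation_function(ins, reference) == INDEL


def test_classify_protein_against_translation_oracle(reference):
    """s/ns must agree with whole-gene translation via Bio.Seq (table 2)."""
    from Bio.Seq import Seq

    import numpy as np

    rng = np.random.default_rng(7)
    proteins = [f for f in reference.features if f.kind == "protein"]
    checked = 0
    for f in proteins:
        # stay clear of gene overlaps so the oracle is single-framed
        others = [g for g in proteins if g is not f]
        for _ in range(4):
            pos = int(rng.integers(f.start, f.end + 1))
            if any(pos in g for g in others):
                continue
            refbase = reference.base_at(pos)
            alt = rng.permutation([b for b in "ACGT" if b != refbase])[0]
            m = Mutation(
                position=pos,
                ref=refbase,
                derived=str(alt),
                kind=TRANSITION if alt in {"A": "G", "G": "A", "C": "T", "T": "C"}[refbase] else TRANSVERSION,
            )
            got = classify_mutation_function(m, reference)
            # oracle: translate the full (codon-padded) gene before/after
            n_codons = (f.end - f.start + 1 + 2) // 3
            span = [f.start + i for i in range(3 * n_codons)]
            gene_ref = "".join(reference.base_at(p) for p in span)
            seq = list(gene_ref)
            seq[pos - f.start] = str(alt)
            gene_alt = "".join(seq)
            if f.strand == "L":
                span_l = [f.end - i for i in range(3 * n_codons)]
                gene_ref = str(Seq("".join(reference.base_at(p) for p in reversed(span_l))).reverse_complement())
                seq = {p: reference.base_at(p) for p in span_l}
                seq[pos] = str(alt)
                gene_alt = str(Seq("".join(seq[p] for p in reversed(span_l))).reverse_complement())
            aa_ref = str(Seq(gene_ref).translate(table=2))
            aa_alt = str(Seq(gene_alt).translate(table=2))
            expected = SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
            assert got == expected, (f.name, pos, refbase, alt)
            checked += 1
    assert checked >= 20


def test_classify_never_s_ns_outside_proteins(reference):
    import numpy as np

    rng = np.random.default_rng(3)
    protein_pos = set()
    for f in reference.features:
        if f.kind == "protein":
            protein_pos.update(range(f.start, f.end + 1))
    for _ in range(200):
        pos = int(rng.integers(577, 16024))
        if pos in protein_pos:
            continue
        m = parse_mutation_token(str(pos), reference)[0]
        assert classify_mutation_function(m, reference) not in (SYNONYMOUS, NONSYNONYMOUS)


# --- exclusion filter -----------------------------------------------------


def test_exclusion_filter_caption_list(reference):
    prof = VariantProfile(
        "s", FULL_COVERAGE, parse_tokens("16182C 16183C 16189 16519", reference)
    )
    out = apply_exclusion_filter(prof)
    assert [format_mutation(m) for m in out.mutations] == ["16189"]


def test_exclusion_filter_c_stretch(reference):
    prof = VariantProfile("s", FULL_COVERAGE, parse_tokens("309.1C 315.1C 16223", reference))
    out = apply_exclusion_filter(prof)
    assert [format_mutation(m) for m in out.mutations] == ["16223"]


def test_exclusion_filter_ac_indels_and_16193_insertions(reference):
    prof = VariantProfile(
        "s", FULL_COVERAGE, parse_tokens("515d 522d 16193.1C 16193.2C 73", reference)
    )
    out = apply_exclusion_filter(prof)
    assert [format_mutation(m) for m in out.mutations] == ["73"]


def test_exclusion_filter_keeps_substitutions_in_305_region(reference):
    # only length polymorphism (indels) is dropped in 303-315
    tok = "310"
    prof = VariantProfile("s", FULL_COVERAGE, parse_tokens(tok, reference))
    assert apply_exclusion_filter(prof).mutations == prof.mutations


def test_exclusion_filter_empty(reference):
    prof = VariantProfile("s", FULL_COVERAGE, [])
    assert apply_exclusion_filter(prof).mutations == []


# --- variant table IO -----------------------------------------------------


def test_variant_table_round_trip(tmp_path, reference):
    profiles = [
        VariantProfile("S1", [(16024, 407)], parse_tokens("16189 73", reference)),
        VariantProfile("S2", FULL_COVERAGE, parse_tokens("8281-8289d 16172", reference)),
        VariantProfile("S3", [(16024, 407)], []),
    ]
    path = tmp_path / "variants.tsv"
    write_variant_table(profiles, str(path))
    back = read_variant_table(str(path), reference)
    assert [p.sample_id for p in back] == ["S1", "S2", "S3"]
    for a, b in zip(profiles, back):
        assert a.covered == b.covered
        assert a.keys == b.keys


def test_variant_table_requires_header(tmp_path, reference):
    path = tmp_path / "bad.tsv"
    path.write_text("S1\t1-100\t73\n")
    with pytest.raises(ValueError):
        read_variant_table(str(path), reference)
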