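import pytest
from hypothesis import given
from hypothesis import strategies as st

from cox_oracle import brute_force_cascade
from sfdkit import (
    CascadeStep,
    Namespace,
    NamespaceMismatchError,
    ProteinID,
    ProteinSet,
    StepKind,
    UnresolvableReferenceError,
    intersect,
    iterate_subfunction,
    run_cascade,
    subtract,
)

UNIVERSE = [f"G{i:02d}" for i in range(50)]


def pset(label, symbols):
    return ProteinSet.from_symbols(label, symbols)


def values(ps):
    return set(ps.values())


class TestBinaryOps:
    def test_subtract_removes_reference_members(self):
        out = subtract(pset("x", "ABCDE"), pset("ref", "BD"))
        assert values(out) == {"A", "C", "E"}

    def test_subtract_identity_and_annihilation(self):
        x = pset("x", "ABC")
        assert values(subtract(x, pset("e", ""))) == {"A", "B", "C"}
        assert values(subtract(x, x)) == set()

    def test_intersect_keeps_common_members(self):
        out = intersect(pset("y", "ACE"), pset("ref", "ABE"))
        assert values(out) == {"A", "E"}

    def test_intersect_idempotent_and_empty(self):
        y = pset("y", "ACE")
        assert values(intersect(y, y)) == {"A", "C", "E"}
        assert values(intersect(y, pset("e", ""))) == set()

    def test_subfunction_is_intersection_with_tagged_provenance(self):
        out = iterate_subfunction(pset("z", "AE"), pset("sub", "E"))
        assert values(out) == {"E"}
        assert out.provenance[-1].op == "subfunction"

    def test_namespace_mismatch_rejected(self):
        x = pset("x", "ABC")
        accs = ProteinSet.from_ids(
            "ref", [ProteinID(Namespace.UNIPROT_ACCESSION, "P00001")]
        )
        with pytest.raises(NamespaceMismatchError):
            subtract(x, accs)

    def test_provenance_counts_track_cardinality(self):
        out = intersect(subtract(pset("x", "ABCDE"), pset("s", "AB")), pset("f", "CD"))
        assert [(r.before, r.after) for r in out.provenance] == [(5, 3), (3, 2)]


class TestCascade:
    def test_funnel_counts_and_final_members(self):
        x = pset("x", [chr(ord("A") + i) for i in range(10)])  # A..J
        refs = {"s": pset("s", "AB"), "f": pset("f", "CDEZ")}
        report = run_cascade(
            x,
            [CascadeStep(StepKind.SUBTRACT, "s"), CascadeStep(StepKind.INTERSECT, "f")],
            refs,
        )
        assert report.counts == [10, 8, 3]
        assert report.final_members == ["C", "D", "E"]
        assert report.steps[0].removed_members == ["A", "B"]

    def test_unresolvable_reference_names_the_label(self):
        with pytest.raises(UnresolvableReferenceError, match="ghost"):
            run_cascade(pset("x", "AB"), [CascadeStep(StepKind.SUBTRACT, "ghost")], {})

    def test_empty_intermediate_sets_propagate(self):
        refs = {"all": pset("all", "AB"), "f": pset("f", "A")}
        report = run_cascade(
            pset("x", "AB"),
            [CascadeStep(StepKind.SUBTRACT, "all"), CascadeStep(StepKind.INTERSECT, "f")],
            refs,
        )
        assert report.counts == [2, 0, 0]
        assert report.final_members == []


cascade_strategy = st.tuples(
    st.sets(st.sampled_from(UNIVERSE), max_size=50),
    st.lists(
        st.tuples(
            st.sampled_from(["subtract", "intersect"]),
            st.sets(st.sampled_from(UNIVERSE), max_size=50),
        ),
        max_size=5,
    ),
)


@given(cascade_strategy)
def test_cascade_matches_brute_force_and_conserves(case):
    """Final set equals per-element evaluation; retained+removed conserved."""
    start, raw_steps = case
    x = pset("x", start)
    refs = {f"r{i}": pset(f"r{i}", members) for i, (_, members) in enumerate(raw_steps)}
    steps = [CascadeStep(StepKind(kind), f"r{i}") for i, (kind, _) in enumerate(raw_steps)]
    report = run_cascade(x, steps, refs)

    expected = brute_force_cascade(
        UNIVERSE, set(start), [(k, set(m)) for k, m in raw_steps]
    )
    assert set(report.final_members) == expected
    prev = report.input_size
    for step in report.steps:
        assert step.retained + step.removed == prev
        assert step.retained <= prev  # monotone shrinkage
        prev = step.retained
    assert len(report.final_members) == prev


@given(cascade_strategy, st.randoms(use_true_random=False))
def test_final_set_is_order_invariant(case, rand):
    """Permuting cascade steps never changes the final member set."""
    start, raw_steps = case
    x = pset("x", start)
    refs = {f"r{i}": pset(f"r{i}", members) for i, (_, members) in enumerate(raw_steps)}
    steps = [CascadeStep(StepKind(kind), f"r{i}") for i, (kind, _) in enumerate(raw_steps)]
    baseline = run_cascade(x, steps, refs).final_members
    shuffled = list(steps)
    rand.shuffle(shuffled)
    assert run_cascade(x, shuffled, refs).final_members == baseline
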