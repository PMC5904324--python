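import pytest

from dichokey.editor import (
    EditError,
    RenumberRefusedError,
    append_key,
    copy_couplet,
    cut_couplet,
    insert_couplet,
    move_couplet,
    paste_couplet,
    remove_couplet,
    renumber,
    split_polytomous,
)
from dichokey.fixtures import FixtureSpec, generate_key
from dichokey.keyio import to_text
from dichokey.model import Couplet, Endpoint, Key, Lead, Pointer, unique_endpoints
from dichokey.validator import is_valid, validate
from oracles import enumerate_transcripts


def issue_codes(key):
    return [i.code for i in validate(key)]


class TestInsert:
    def test_insert_into_empty_key_creates_dummy_couplet_1(self):
        key = insert_couplet(Key(), 0)
        assert [c.number for c in key.couplets] == [1]
        assert [l.reference for l in key.couplets[0].leads] == [
            Endpoint("?"),
            Endpoint("?"),
        ]

    def test_insert_takes_max_plus_one_without_renumbering(self, chain_key):
        key = insert_couplet(chain_key, 1)
        assert [c.number for c in key.couplets] == [1, 4, 2, 3]
        assert "not-consecutive" not in issue_codes(key)  # 1..4 all present

    def test_consecutive_inserts_keep_numbers_unique(self, chain_key):
        key = insert_couplet(insert_couplet(chain_key, 0), 0)
        numbers = key.numbers()
        assert len(set(numbers)) == len(numbers)
        assert {4, 5} <= set(numbers)

    def test_position_out_of_range(self, chain_key):
        with pytest.raises(EditError):
            insert_couplet(chain_key, 9)


class TestRemove:
    def test_remove_leaves_dangling_pointer_for_validator(self, chain_key):
        key = remove_couplet(chain_key, 3)
        assert len(key.couplets) == 2
        dangling = [i for i in validate(key) if i.code == "dangling-pointer"]
        assert [i.couplets for i in dangling] == [(2,)]

    def test_remove_only_couplet_gives_empty_key(self, minimal_key):
        assert remove_couplet(minimal_key, 1).couplets == []

    def test_remove_unreferenced_couplet_adds_no_new_issues(self, chain_key):
        grown = insert_couplet(chain_key, 3)  # dummy couplet 4, unreferenced
        before = {(i.code, i.couplets) for i in validate(chain_key)}
        after = {(i.code, i.couplets) for i in validate(remove_couplet(grown, 4))}
        assert after == before

    def test_remove_missing_number(self, chain_key):
        with pytest.raises(EditError):
            remove_couplet(chain_key, 7)


class TestMoveAndCopy:
    def test_move_permutes_rows_only(self, chain_key):
        key = move_couplet(chain_key, 0, 2)
        assert [c.number for c in key.couplets] == [2, 3, 1]
        assert {i.code for i in validate(key)} == {
            i.code for i in validate(chain_key)
        }

    def test_move_onto_own_position_is_identity(self, chain_key):
        assert to_text(move_couplet(chain_key, 1, 1)) == to_text(chain_key)

    def test_copy_duplicates_verbatim_with_fresh_number(self, balanced_key):
        key = copy_couplet(balanced_key, 2, 3)
        assert [c.number for c in key.couplets] == [1, 2, 3, 4]
        copied = key.couplets[3]
        assert copied.number == 4
        assert [l.reference for l in copied.leads] == [Endpoint("A"), Endpoint("B")]
        codes = issue_codes(key)
        assert "reticulated-endpoint" in codes
        assert "unreferenced-couplet" in codes  # nothing points at the copy

    def test_copy_then_remove_copy_restores_validation(self, balanced_key):
        key = remove_couplet(copy_couplet(balanced_key, 2, 3), 4)
        assert [str(i) for i in validate(key)] == [str(i) for i in validate(balanced_key)]

    def test_copying_a_pointer_couplet_reticulates_its_targets(self, balanced_key):
        key = copy_couplet(balanced_key, 1, 3)
        targets = {
            i.couplets[0] for i in validate(key) if i.code == "reticulated-couplet"
        }
        assert targets == {2, 3}

    def test_cut_paste_roundtrip_renumbers_payload(self, chain_key):
        cut, payload = cut_couplet(chain_key, 2)
        pasted = paste_couplet(cut, payload, 1)
        assert [c.number for c in pasted.couplets] == [1, 4, 3]
        assert [l.text for l in pasted.couplets[1].leads] == ["Dark", "Pale"]


class TestAppend:
    def test_offsets_numbers_and_pointers(self, balanced_key, chain_key):
        merged = append_key(chain_key, balanced_key)
        assert [c.number for c in merged.couplets] == [1, 2, 3, 4, 5, 6]
        appended_root = merged.couplets[3]
        assert [l.reference for l in appended_root.leads] == [Pointer(5), Pointer(6)]

    def test_exactly_one_unreferenced_couplet_issue(self, balanced_key, chain_key):
        merged = append_key(chain_key, balanced_key)
        unreferenced = [i for i in validate(merged) if i.code == "unreferenced-couplet"]
        assert [i.couplets for i in unreferenced] == [(4,)]
        # The appended subtree is also (correctly) unreachable from couplet 1
        # until the user adds a pointer lead into its root.
        unreachable = {
            i.couplets[0] for i in validate(merged) if i.code == "unreachable-couplet"
        }
        assert unreachable == {4, 5, 6}

    def test_append_empty_key_is_identity(self, chain_key):
        assert to_text(append_key(chain_key, Key())) == to_text(chain_key)

    def test_endpoint_sets_union(self, balanced_key, chain_key):
        merged = append_key(chain_key, balanced_key)
        assert set(unique_endpoints(merged)) == set(
            unique_endpoints(chain_key)
        ) | set(unique_endpoints(balanced_key))

    def test_invalid_other_refused(self, chain_key, balanced_key):
        balanced_key.couplets[1].leads[0].reference = Pointer(99)
        with pytest.raises(EditError):
            append_key(chain_key, balanced_key)


class TestRenumber:
    def test_gap_closed_and_pointers_remapped(self):
        key = Key(
            couplets=[
                Couplet(1, [Lead("a", Pointer(2)), Lead("b", Endpoint("A"))]),
                Couplet(2, [Lead("c", Pointer(4)), Lead("d", Endpoint("B"))]),
                Couplet(4, [Lead("e", Endpoint("C")), Lead("f", Endpoint("D"))]),
            ]
        )
        out = renumber(key)
        assert [c.number for c in out.couplets] == [1, 2, 3]
        assert out.couplets[1].leads[0].reference == Pointer(3)
        assert is_valid(out)

    def test_fixpoint_on_consecutive_key(self, chain_key):
        assert to_text(renumber(chain_key)) == to_text(chain_key)

    def test_row_order_defines_new_numbers(self, chain_key):
        moved = move_couplet(chain_key, 2, 0)  # rows: 3, 1, 2
        out = renumber(moved)
        assert [c.number for c in out.couplets] == [1, 2, 3]
        # Old couplet 1 (the logical root) is now number 2.
        assert out.couplets[1].leads[0].text == "Large"

    @pytest.mark.parametrize("breaker", ["dup-number", "dangling-pointer"])
    def test_refused_while_graph_ill_defined(self, chain_key, breaker):
        if breaker == "dup-number":
            chain_key.couplets[2].number = 2
        else:
            chain_key.couplets[2].leads[0].reference = Pointer(9)
        with pytest.raises(RenumberRefusedError) as err:
            renumber(chain_key)
        assert breaker in err.value.blocking_codes


class TestSplitPolytomous:
    @pytest.fixture
    def trichotomy(self):
        return Key(
            couplets=[
                Couplet(
                    1,
                    [
                        Lead("Leaves opposite", Endpoint("A")),
                        Lead("Leaves alternate", Endpoint("B")),
                        Lead("Leaves whorled", Endpoint("C")),
                    ],
                )
            ]
        )

    def test_three_leads_become_two_couplets(self, trichotomy):
        out = split_polytomous(trichotomy, 1)
        assert len(out.couplets) == 2
        first, second = out.couplets
        assert [len(c.leads) for c in out.couplets] == [2, 2]
        assert first.leads[0].reference == Endpoint("A")
        assert first.leads[1].text == "Leaves alternate OR Leaves whorled"
        assert first.leads[1].reference == Pointer(2)
        assert [l.reference for l in second.leads] == [Endpoint("B"), Endpoint("C")]

    def test_endpoint_set_preserved_and_renumber_repairs(self, trichotomy):
        before = unique_endpoints(trichotomy)
        out = renumber(split_polytomous(trichotomy, 1))
        assert unique_endpoints(out) == before
        assert "bad-lead-count" not in issue_codes(out)
        assert is_valid(out)

    def test_five_leads_become_four_couplets(self):
        leads = [Lead(f"state {i}", Endpoint(f"T{i}")) for i in range(1, 6)]
        key = Key(couplets=[Couplet(1, leads)])
        out = split_polytomous(key, 1)
        assert len(out.couplets) == 4
        assert unique_endpoints(out) == [f"T{i}" for i in range(1, 6)]
        assert is_valid(renumber(out))

    def test_chain_sits_directly_after_original_with_fresh_numbers(self):
        leads = [Lead(f"s{i}", Endpoint(f"T{i}")) for i in range(1, 5)]
        key = Key(
            couplets=[
                Couplet(1, [Lead("a", Pointer(2)), Lead("b", Pointer(3))]),
                Couplet(2, leads),
                Couplet(3, [Lead("c", Endpoint("X")), Lead("d", Endpoint("Y"))]),
            ]
        )
        out = split_polytomous(key, 2)
        assert [c.number for c in out.couplets] == [1, 2, 4, 5, 3]

    def test_dichotomous_couplet_is_noop(self, chain_key):
        assert to_text(split_polytomous(chain_key, 2)) == to_text(chain_key)

    def test_missing_couplet_is_error(self, chain_key):
        with pytest.raises(EditError):
            split_polytomous(chain_key, 42)


class TestPurityAndTranscripts:
    def test_operations_do_not_mutate_input(self, chain_key):
        snapshot = to_text(chain_key)
        insert_couplet(chain_key, 0)
        remove_couplet(chain_key, 3)
        move_couplet(chain_key, 0, 2)
        copy_couplet(chain_key, 1, 0)
        renumber(chain_key)
        split_polytomous(chain_key, 1)
        assert to_text(chain_key) == snapshot

    @pytest.mark.parametrize("seed", range(10))
    def test_transcripts_invariant_under_move_plus_renumber(self, seed):
        key = generate_key(FixtureSpec(couplets=9, reticulation=0.2, seed=seed))
        before = enumerate_transcripts(key)
        # Row 0 stays put: moving the root row would deliberately change the
        # key's starting couplet, which is a semantic edit, not a renumbering.
        moved = move_couplet(key, 1 + seed % 8, 1 + (seed * 5 + 3) % 8)
        out = renumber(moved)
        assert is_valid(out)
        assert enumerate_transcripts(out) == before

    def test_lead_texts_never_silently_changed(self, balanced_key):
        from collections import Counter

        original = Counter(l.text for _, _, l in balanced_key.iter_leads())
        for op in (
            lambda k: insert_couplet(k, 0),
            lambda k: copy_couplet(k, 2, 0),
            lambda k: move_couplet(k, 0, 2),
            lambda k: renumber(k),
        ):
            result = Counter(l.text for _, _, l in op(balanced_key).iter_leads())
            assert result & original == original  # every original text retained
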