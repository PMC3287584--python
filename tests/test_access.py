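"""Authentication, the role/ownership permission matrix, and the audit trail."""

import pytest

from protrack import (AuthenticationError, DuplicateError, PermissionDenied,
                      Store, access, tracking)

# ---------------------------------------------------------------------------
# authentication


class TestAuthentication:
    def test_register_then_authenticate(self, store):
        access.register_user(store, "newbie", "s3cret")
        assert access.authenticate(store, "newbie", "s3cret")

    def test_wrong_password_and_unknown_login_fail_identically(self, store):
        with pytest.raises(AuthenticationError) as wrong_pw:
            access.authenticate(store, "gloria", "nope")
        with pytest.raises(AuthenticationError) as unknown:
            access.authenticate(store, "whoever", "nope")
        assert str(wrong_pw.value) == str(unknown.value)

    def test_duplicate_login_rejected(self, store):
        with pytest.raises(DuplicateError):
            access.register_user(store, "gloria", "again")

    def test_password_stored_only_as_salted_hash(self, store):
        row = store.conn.execute(
            "SELECT password_hash FROM users WHERE login='gloria'").fetchone()
        assert "pw-g" not in row["password_hash"]
        assert row["password_hash"].startswith("pbkdf2_sha256$")

    def test_demo_guest_account_authenticates_with_guest_role(self, demo_store):
        assert access.authenticate(demo_store, "guest", "guest")
        project = demo_store.get_project_by_name("SmProteome")
        assert demo_store.membership_role("guest", project.project_id) == \
            "GUEST"


# ---------------------------------------------------------------------------
# permission matrix

@pytest.fixture
def matrix_store(tmp_path):
    """Two projects; project 1 has a coordinator, two researchers and a
    guest; project 2 holds the 'other project' experiment."""
    s = Store(tmp_path / "m.db")
    for login in ("coord", "res_owner", "res_peer", "guesty", "other_coord"):
        access.register_user(s, login, f"pw-{login}")
    p1 = s.create_project("Main", "", "coord", guest_visible=True)
    s.add_member(p1.project_id, "res_owner", "RESEARCHER")
    s.add_member(p1.project_id, "res_peer", "RESEARCHER")
    s.add_member(p1.project_id, "guesty", "GUEST")
    p2 = s.create_project("Foreign", "", "other_coord")
    own = s.create_experiment(p1.project_id, "PREP", "own", "res_owner",
                              "2011-01-01")
    teammate = s.create_experiment(p1.project_id, "PREP", "teammate",
                                   "res_peer", "2011-01-02")
    foreign = s.create_experiment(p2.project_id, "PREP", "foreign",
                                  "other_coord", "2011-01-03")
    s.exp = {"own": own.id, "teammate": teammate.id, "foreign": foreign.id}
    yield s
    s.close()


# (user, target, view allowed, view scope, edit allowed)
MATRIX = [
    # guests: stub view in guest-visible projects only, never edit
    ("guesty", "own", True, "stub", False),
    ("guesty", "teammate", True, "stub", False),
    ("guesty", "foreign", False, None, False),
    # researcher: sees all project experiments even if inserted by other
    # members, edits only their own, sees nothing outside their projects
    ("res_owner", "own", True, "full", True),
    ("res_owner", "teammate", True, "full", False),
    ("res_owner", "foreign", False, None, False),
    # coordinator: can access and update all data of their projects
    ("coord", "own", True, "full", True),
    ("coord", "teammate", True, "full", True),
    ("coord", "foreign", False, None, False),
]


@pytest.mark.parametrize(
    "user,target,view_ok,scope,edit_ok", MATRIX,
    ids=[f"{u}-vs-{t}" for u, t, *_ in MATRIX])
def test_permission_matrix_cell(matrix_store, user, target, view_ok, scope,
                                edit_ok):
    exp_id = matrix_store.exp[target]
    view = access.can_view(matrix_store, user, exp_id)
    edit = access.can_edit(matrix_store, user, exp_id)
    assert (view.allowed, view.scope) == (view_ok, scope)
    assert edit.allowed == edit_ok


def test_role_monotonicity(matrix_store):
    """Granting a higher role never removes a right on the same object."""
    rank = {"guesty": 0, "res_peer": 1, "coord": 2}
    for target in ("own", "teammate", "foreign"):
        exp_id = matrix_store.exp[target]
        views = [access.can_view(matrix_store, u, exp_id).allowed
                 for u in ("guesty", "res_peer", "coord")]
        edits = [access.can_edit(matrix_store, u, exp_id).allowed
                 for u in ("guesty", "res_peer", "coord")]
        for lower, higher in zip(views, views[1:]):
            assert higher >= lower
        for lower, higher in zip(edits, edits[1:]):
            assert higher >= lower


def test_stub_view_hides_everything_but_id_type_title(matrix_store):
    exp = matrix_store.get_experiment(matrix_store.exp["own"],
                                      actor="guesty")
    assert (exp.id, exp.type, exp.title) == \
        (matrix_store.exp["own"], "PREP", "own")
    assert exp.performed_by == "" and exp.samples == [] \
        and exp.attachments == []


def test_non_member_view_raises(matrix_store):
    with pytest.raises(PermissionDenied):
        matrix_store.get_experiment(matrix_store.exp["foreign"],
                                    actor="res_owner")


def test_visible_set_is_union_over_memberships(matrix_store):
    """No cross-project leakage: what a user can see is exactly their
    projects (plus guest-visible stubs)."""
    all_ids = list(matrix_store.exp.values())
    visible = {u: {i for i in all_ids
                   if access.can_view(matrix_store, u, i).allowed}
               for u in ("res_owner", "other_coord", "guesty")}
    main_ids = {matrix_store.exp["own"], matrix_store.exp["teammate"]}
    assert visible["res_owner"] == main_ids
    assert visible["other_coord"] == {matrix_store.exp["foreign"]}
    assert visible["guesty"] == main_ids  # stubs of the guest-visible project


# ---------------------------------------------------------------------------
# audit trail


class TestAudit:
    def test_create_experiment_appends_create_entry(self, store):
        e = store.create_experiment(1, "PREP", "t", "herbert", "2011-01-01")
        entries = access.audit_log(store, 1)
        assert entries[-1].action == "create"
        assert entries[-1].user == "herbert"
        assert entries[-1].experiment == e.id

    def test_log_ordered_and_counts_mutations(self, store):
        a = store.create_experiment(1, "PREP", "a", "gloria", "2011-01-01")
        b = store.create_experiment(1, "PREP", "b", "gloria", "2011-01-02")
        tracking.link(store, a.id, b.id)
        store.attach_bytes(a.id, b"x", "f.txt", "other")
        entries = access.audit_log(store, 1)
        assert [e.seq for e in entries] == sorted(e.seq for e in entries)
        assert [e.action for e in entries] == \
            ["create", "create", "link", "attach"]

    def test_audit_log_is_coordinator_only(self, store):
        store.create_experiment(1, "PREP", "t", "gloria", "2011-01-01")
        assert access.audit_log(store, 1, actor="gloria")
        with pytest.raises(PermissionDenied):
            access.audit_log(store, 1, actor="herbert")

    def test_denied_view_leaves_a_view_denied_entry(self, matrix_store):
        with pytest.raises(PermissionDenied):
            matrix_store.get_experiment(matrix_store.exp["foreign"],
                                        actor="res_owner")
        p2 = matrix_store.get_project_by_name("Foreign")
        entries = access.audit_log(matrix_store, p2.project_id)
        assert entries[-1].action == "view-denied"
        assert entries[-1].user == "res_owner"
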