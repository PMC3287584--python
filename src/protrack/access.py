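"""Login-based authentication and per-project role authorization.

Three role levels, totally ordered GUEST < RESEARCHER < COORDINATOR, are
granted per project membership:

* GUEST — may see only the id/type/title stub of experiments, and only in
  projects flagged guest-visible;
* RESEARCHER — sees every experiment of their projects, including those
  inserted by other members, but may edit only experiments they performed;
* COORDINATOR — may view and update all data associated with their projects,
  and is the only role allowed to read the project's audit trail.

Non-members see nothing of a project (apart from guest-visible stubs when
they hold a GUEST membership there).  Every mutating operation appends an
immutable audit entry recording who performed which experiment.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass

from .errors import (AuthenticationError, DuplicateError, NotFoundError,
                     PermissionDenied)

ROLE_ORDER = {"GUEST": 0, "RESEARCHER": 1, "COORDINATOR": 2}

_PBKDF2_ITERATIONS = 50_000


@dataclass(frozen=True)
class UserAccount:
    login: str
    display_name: str


@dataclass(frozen=True)
class Decision:
    """Authorization outcome; ``scope`` is 'full' or 'stub' when allowed."""

    allowed: bool
    scope: str | None
    reason: str

    def __bool__(self) -> bool:
        return self.allowed


@dataclass(frozen=True)
class AuditEntry:
    seq: int
    user: str
    action: str
    experiment: int | None
    timestamp: str


def _hash_password(password: str, salt: bytes | None = None) -> str:
    salt = salt if salt is not None else secrets.token_bytes(16)
    digest = hashlib.pbkdf2_hmac("sha256", password.encode(), salt,
                                 _PBKDF2_ITERATIONS)
    return f"pbkdf2_sha256${_PBKDF2_ITERATIONS}${salt.hex()}${digest.hex()}"


def _verify_password(password: str, stored: str) -> bool:
    try:
        _scheme, iters, salt_hex, digest_hex = stored.split("$")
        digest = hashlib.pbkdf2_hmac("sha256", password.encode(),
                                     bytes.fromhex(salt_hex), int(iters))
        return secrets.compare_digest(digest.hex(), digest_hex)
    except (ValueError, TypeError):
        return False


def register_user(store, login: str, password: str,
                  display_name: str = "") -> UserAccount:
    if not login:
        raise AuthenticationError("login must be nonempty")
    if store.user_exists(login):
        raise DuplicateError(f"login {login!r} already registered")
    with store.conn:
        store.conn.execute(
            "INSERT INTO users(login, password_hash, display_name)"
            " VALUES (?,?,?)", (login, _hash_password(password), display_name))
    return UserAccount(login, display_name)


def authenticate(store, login: str, password: str) -> str:
    """Return a session token, or raise a deliberately opaque failure that
    does not reveal whether the login or the password was wrong."""
    row = store.conn.execute(
        "SELECT password_hash FROM users WHERE login=?", (login,)).fetchone()
    if row is None or not _verify_password(password, row["password_hash"]):
        raise AuthenticationError("invalid credentials")
    return secrets.token_hex(16)


def _experiment_context(store, user: str, exp_id: int):
    if not store.user_exists(user):
        raise NotFoundError(f"unknown user {user!r}")
    row = store._experiment_row(exp_id)
    project = store.get_project(row["project_id"])
    role = store.membership_role(user, project.project_id)
    return row, project, role


def can_view(store, user: str, exp_id: int) -> Decision:
    row, project, role = _experiment_context(store, user, exp_id)
    if role in ("RESEARCHER", "COORDINATOR"):
        return Decision(True, "full",
                        f"{role.lower()} member of project {project.name!r}")
    if role == "GUEST":
        if project.guest_visible:
            return Decision(True, "stub",
                            "guest access to a guest-visible project is"
                            " limited to id/type/title")
        return Decision(False, None,
                        f"project {project.name!r} is not guest-visible")
    return Decision(False, None,
                    f"{user!r} is not a member of project {project.name!r}")


def can_edit(store, user: str, exp_id: int) -> Decision:
    row, project, role = _experiment_context(store, user, exp_id)
    if role == "COORDINATOR":
        return Decision(True, "full",
                        f"coordinator of project {project.name!r}")
    if role == "RESEARCHER":
        if row["performed_by"] == user:
            return Decision(True, "full", "researcher editing own experiment")
        return Decision(False, None,
                        "researchers may only edit their own experiments")
    if role == "GUEST":
        return Decision(False, None, "guests may not edit anything")
    return Decision(False, None,
                    f"{user!r} is not a member of project {project.name!r}")


def require_view(store, user: str, exp_id: int) -> None:
    decision = can_view(store, user, exp_id)
    if not decision.allowed:
        store.record_action(user, "view-denied", exp_id)
        raise PermissionDenied(decision.reason)


def require_edit(store, user: str, exp_id: int) -> None:
    decision = can_edit(store, user, exp_id)
    if not decision.allowed:
        raise PermissionDenied(decision.reason)


def require_project_write(store, user: str, project_id: int) -> None:
    role = store.membership_role(user, project_id)
    if role not in ("RESEARCHER", "COORDINATOR"):
        raise PermissionDenied(
            f"{user!r} may not create experiments in project {project_id}")


def audit_log(store, project_id: int, actor: str | None = None
              ) -> list[AuditEntry]:
    """Ordered audit trail of a project, readable by its coordinator only
    (or by anyone in no-auth local mode, ``actor=None``)."""
    project = store.get_project(project_id)
    if actor is not None and store.membership_role(
            actor, project_id) != "COORDINATOR":
        raise PermissionDenied(
            f"audit log of {project.name!r} is coordinator-only")
    exp_ids = [r["id"] for r in store.conn.execute(
        "SELECT id FROM experiments WHERE project_id=?", (project_id,))]
    rows = store.conn.execute(
        "SELECT * FROM audit ORDER BY seq ASC").fetchall()
    wanted = set(exp_ids)
    return [AuditEntry(r["seq"], r["user"], r["action"], r["experiment_id"],
                       r["timestamp"])
            for r in rows
            if r["experiment_id"] in wanted]
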