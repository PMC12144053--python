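"""Social-media app categorization and coder-agreement statistics.

Four categorization schemes are carried side by side:

``sns``
    Research-coded narrow "social networking" apps: platforms whose primary
    goal is social networking (user-generated content, public networking,
    synchronous and asynchronous interaction), plus community/affinity
    forums.
``broad``
    Research-coded broad "social media": every SNS app plus platforms with
    user-generated content or public synchronous interaction but without the
    full social-networking feature set (e.g. video-sharing or live-stream
    apps).
``google_play``
    Apps the Google Play store itself files under its social genre.
``popular``
    The small set of survey-defined "popular social media" platforms
    (Pew Research Center list).

Membership is carried as flags keyed by the Android package name, which is
canonical, so matching is exact and case-sensitive.  The packaged reference
key reflects the apps observed in a 2020 adolescent cohort; app
functionality drifts, so the key file carries a schema marker and is meant
to be re-issued over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "CategoryKey",
    "KeyError_",
    "DuplicatePackageError",
    "KeyInvariantError",
    "load_key",
    "reference_key",
    "categorize",
    "category_members",
    "inter_rater_kappa",
]

#: Canonical scheme names, in the order used throughout the package.
CATEGORIES = ("sns", "broad", "google_play", "popular")

_KEY_COLUMNS = ["app_label", "package_name", "sns", "broad", "google_play", "popular"]


class KeyError_(ValueError):
    """Base error for malformed category keys."""


class DuplicatePackageError(KeyError_):
    """A package name appears on more than one key row."""

    def __init__(self, duplicates: list[str]):
        self.duplicates = duplicates
        super().__init__(f"duplicate package names in key: {', '.join(duplicates)}")


class KeyInvariantError(KeyError_):
    """A key row violates the scheme-nesting invariants."""


@dataclass(frozen=True)
class CategoryKey:
    """Package -> category-membership map.

    The underlying table has one row per app with boolean flags for each
    scheme.  Two nesting invariants hold by construction: every ``sns`` app
    is also ``broad``, and every ``popular`` app is also ``broad``.  The
    Play-store scheme is independent (Play-only apps exist).
    """

    table: pd.DataFrame
    schema_version: int = 1

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, package_name: str) -> bool:
        return package_name in set(self.table["package_name"])

    def label_for(self, package_name: str) -> str | None:
        """Human-readable app label for a package, or None if unknown."""
        hit = self.table.loc[self.table["package_name"] == package_name, "app_label"]
        return None if hit.empty else str(hit.iloc[0])


def _validate_key_table(table: pd.DataFrame) -> None:
    dupes = table["package_name"][table["package_name"].duplicated()].unique().tolist()
    if dupes:
        raise DuplicatePackageError(sorted(dupes))
    sns_not_broad = table.loc[(table["sns"] == 1) & (table["broad"] == 0), "package_name"]
    if len(sns_not_broad):
        raise KeyInvariantError(
            "sns apps must also be broad: " + ", ".join(sns_not_broad)
        )
    pop_not_broad = table.loc[(table["popular"] == 1) & (table["broad"] == 0), "package_name"]
    if len(pop_not_broad):
        raise KeyInvariantError(
            "popular apps must also be broad: " + ", ".join(pop_not_broad)
        )


def load_key(path: str | Path) -> CategoryKey:
    """Read a category key from its delimited-text dialect.

    The dialect is UTF-8 CSV with header
    ``app_label,package_name,sns,broad,google_play,popular`` and ``1``/``0``
    flags; lines starting with ``#`` are treated as comments (the packaged
    key carries its schema version there).

    Raises
    ------
    DuplicatePackageError
        If a package name occurs more than once.
    KeyInvariantError
        If an ``sns`` or ``popular`` row is not also ``broad``.
    """
    table = pd.read_csv(path, comment="#", dtype={"app_label": str, "package_name": str})
    missing = [c for c in _KEY_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError_(f"key file missing columns: {', '.join(missing)}")
    table = table[_KEY_COLUMNS].copy()
    for flag in CATEGORIES:
        values = set(table[flag].unique()) - {0, 1}
        if values:
            raise KeyError_(f"column {flag!r} must contain only 0/1, found {sorted(values)}")
        table[flag] = table[flag].astype(np.int8)
    _validate_key_table(table)
    return CategoryKey(table=table.reset_index(drop=True))


def reference_key() -> CategoryKey:
    """The packaged 44-app reference key (2020 study-period categorization)."""
    source = resources.files("sm_phenotype.data").joinpath("social_media_key.csv")
    with resources.as_file(source) as path:
        return load_key(path)


def categorize(package_name: str, key: CategoryKey) -> frozenset[str]:
    """Return the set of scheme names a package belongs to.

    An unknown package returns the empty set: not social media under any
    scheme is a valid outcome, not an error.
    """
    row = key.table.loc[key.table["package_name"] == package_name]
    if row.empty:
        return frozenset()
    row = row.iloc[0]
    return frozenset(c for c in CATEGORIES if row[c] == 1)


def category_members(key: CategoryKey, category: str) -> frozenset[str]:
    """All package names flagged for one scheme.

    Raises
    ------
    ValueError
        If ``category`` is not one of the four scheme names.
    """
    if category not in CATEGORIES:
        raise ValueError(
            f"unknown category {category!r}; expected one of {', '.join(CATEGORIES)}"
        )
    return frozenset(key.table.loc[key.table[category] == 1, "package_name"])


# ---------------------------------------------------------------------------
# Multi-coder agreement
# ---------------------------------------------------------------------------

def _as_rating_matrix(ratings) -> np.ndarray:
    mat = pd.DataFrame(ratings)
    if mat.isna().any().any():
        raise ValueError("rating matrix must have no missing cells")
    return mat.to_numpy()


def inter_rater_kappa(ratings) -> float:
    """Chance-corrected agreement among coders assigning nominal labels.

    ``ratings`` is an items x raters table (DataFrame or array) of nominal
    labels.  With exactly two raters this is Cohen's kappa,

        kappa = (p_o - p_e) / (1 - p_e),

    where ``p_o`` is observed agreement and ``p_e`` the product-marginal
    chance agreement.  With three or more raters it is Fleiss' kappa: with
    ``n_ij`` the number of raters placing item i in category j, r raters and
    N items,

        P_i   = (sum_j n_ij^2 - r) / (r (r - 1))
        p_j   = sum_i n_ij / (N r)
        kappa = (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2).

    When every cell carries one identical label both expected and observed
    agreement are 1 and the ratio is 0/0; by convention the function returns
    1.0 (perfect agreement).  Values lie in [-1, 1].

    Raises
    ------
    ValueError
        Fewer than 2 raters or fewer than 2 items, or missing cells.
    """
    mat = _as_rating_matrix(ratings)
    n_items, n_raters = mat.shape
    if n_raters < 2:
        raise ValueError("inter-rater agreement requires at least 2 raters")
    if n_items < 2:
        raise ValueError("inter-rater agreement requires at least 2 items")

    labels, coded = np.unique(mat, return_inverse=True)
    coded = coded.reshape(mat.shape)
    n_cats = len(labels)
    if n_cats == 1:
        return 1.0

    if n_raters == 2:
        a, b = coded[:, 0], coded[:, 1]
        p_o = float(np.mean(a == b))
        pa = np.bincount(a, minlength=n_cats) / n_items
        pb = np.bincount(b, minlength=n_cats) / n_items
        p_e = float(pa @ pb)
    else:
        counts = np.zeros((n_items, n_cats))
        for j in range(n_raters):
            counts[np.arange(n_items), coded[:, j]] += 1
        p_i = (np.sum(counts**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))
        p_o = float(np.mean(p_i))
        p_j = counts.sum(axis=0) / (n_items * n_raters)
        p_e = float(np.sum(p_j**2))

    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
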