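"""Codelist handling and translation between clinical coding frameworks.

UK primary-care records arrive coded in several frameworks: Read v2 and
Clinical Terms Version 3 (CTV3) for clinical events, and BNF chapters,
DM+D identifiers or CPRD product codes for prescriptions.  Condition
codelists curated in one framework have to be translated into whichever
frameworks a target dataset actually uses before any phenotyping can
happen.  Translation here follows the over-inclusive ("sensitive")
convention: a one-to-many lookup entry contributes *all* of its target
codes, and an audit table accounts for every source code — mapped,
unmapped or manually overridden — so that a human reviewer can prune
erroneous inclusions afterwards.  Nothing is ever silently dropped.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class Framework(str, enum.Enum):
    """Coding frameworks encountered in UK primary-care extracts."""

    READ2 = "READ2"
    CTV3 = "CTV3"
    PRODCODE = "PRODCODE"
    BNF = "BNF"
    DMD = "DMD"


class Domain(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    PRESCRIPTION = "prescription"
    TEST = "test"


#: Frameworks admissible for each record domain.
DOMAIN_FRAMEWORKS: dict[Domain, frozenset[Framework]] = {
    Domain.DIAGNOSIS: frozenset({Framework.READ2, Framework.CTV3}),
    Domain.TEST: frozenset({Framework.READ2, Framework.CTV3}),
    Domain.PRESCRIPTION: frozenset({Framework.PRODCODE, Framework.BNF, Framework.DMD}),
}


class CodemapError(ValueError):
    """Configuration or format problem in codelists / lookup tables."""


class MappingStatus(str, enum.Enum):
    MAPPED = "mapped"
    UNMAPPED = "unmapped"
    MANUAL_OVERRIDE = "manual_override"
    FLAGGED = "flagged"  # used for audit annotation of multi-source targets


@dataclass(frozen=True)
class Codelist:
    """A set of codes defining one condition in one framework and domain.

    Codes are stored whitespace-trimmed but case-preserved: Read v2 and
    CTV3 are case-sensitive hierarchies.
    """

    condition_id: str
    framework: Framework
    domain: Domain
    codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.framework not in DOMAIN_FRAMEWORKS[self.domain]:
            raise CodemapError(
                f"framework {self.framework.value} is not valid for "
                f"domain {self.domain.value}"
            )
        stripped = frozenset(c.strip() for c in self.codes if c and c.strip())
        object.__setattr__(self, "codes", stripped)

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class MappingAudit:
    """Per-source-code account of one mapping run.

    ``sources`` has one row per source code with columns
    (source_code, status, targets, n_targets, flagged); ``flagged_targets``
    lists target codes reached from more than one source code — candidates
    for manual review under a sensitive mapping policy.
    """

    sources: pd.DataFrame
    flagged_targets: pd.DataFrame

    @property
    def n_unmapped(self) -> int:
        return int((self.sources["status"] == MappingStatus.UNMAPPED.value).sum())

    @property
    def unmapped_codes(self) -> frozenset[str]:
        rows = self.sources[self.sources["status"] == MappingStatus.UNMAPPED.value]
        return frozenset(rows["source_code"])


def load_codelist(
    path: str | Path,
    framework: Framework | str,
    domain: Domain | str,
    condition_id: str | None = None,
) -> Codelist:
    """Read one condition's codelist from a delimited-text file.

    The file must carry ``code`` and ``condition_id`` columns (extra
    columns are ignored).  Duplicate codes are dropped with a logged
    count; an empty file yields an empty codelist and a warning rather
    than an error.
    """
    framework = Framework(framework)
    domain = Domain(domain)
    frame = pd.read_csv(path, dtype=str, comment="#")
    missing = {"code", "condition_id"} - set(frame.columns)
    if missing:
        raise CodemapError(f"{path}: missing required column(s) {sorted(missing)}")
    if condition_id is not None:
        frame = frame[frame["condition_id"] == condition_id]
    else:
        ids = frame["condition_id"].dropna().unique()
        if len(ids) > 1:
            raise CodemapError(
                f"{path}: multiple condition ids {sorted(ids)}; pass condition_id"
            )
        condition_id = ids[0] if len(ids) == 1 else "unknown"
    raw = [c.strip() for c in frame["code"].dropna() if c.strip()]
    codes = frozenset(raw)
    n_dup = len(raw) - len(codes)
    logger.info(
        "loaded codelist %s (%s/%s): %d codes, %d duplicates dropped",
        condition_id, framework.value, domain.value, len(codes), n_dup,
    )
    if not codes:
        warnings.warn(
            f"codelist for {condition_id} from {path} is empty", stacklevel=2
        )
    return Codelist(condition_id, framework, domain, codes)


def load_codelist_table(
    path: str | Path, framework: Framework | str, domain: Domain | str
) -> dict[str, Codelist]:
    """Read a multi-condition codelist file into one Codelist per condition."""
    framework = Framework(framework)
    domain = Domain(domain)
    frame = pd.read_csv(path, dtype=str, comment="#")
    missing = {"code", "condition_id"} - set(frame.columns)
    if missing:
        raise CodemapError(f"{path}: missing required column(s) {sorted(missing)}")
    out: dict[str, Codelist] = {}
    for cid, grp in frame.dropna(subset=["code", "condition_id"]).groupby("condition_id"):
        out[str(cid)] = Codelist(
            str(cid), framework, domain, frozenset(c.strip() for c in grp["code"])
        )
    return out


def _normalise_pairs(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = {"source_code", "target_code"} - set(frame.columns)
    if missing:
        raise CodemapError(f"{what}: missing required column(s) {sorted(missing)}")
    out = frame[["source_code", "target_code"]].copy()
    out["source_code"] = out["source_code"].astype(str).str.strip()
    out["target_code"] = out["target_code"].astype(str).str.strip()
    out = out[(out["source_code"] != "") & (out["target_code"] != "")]
    return out.drop_duplicates()


def map_codes(
    source: Codelist,
    lookup: pd.DataFrame,
    target_framework: Framework | str,
    overrides: pd.DataFrame | None = None,
    source_framework_column: str = "source_framework",
) -> tuple[Codelist, MappingAudit]:
    """Translate ``source`` into ``target_framework`` via a lookup table.

    ``lookup`` (and the optional ``overrides`` table, which wins on
    conflict) hold one (source_code, target_code) pair per row.  The
    returned codelist is the deduplicated union of all targets of mapped
    source codes; the audit classifies every source code into exactly one
    of {mapped, manual_override, unmapped} and flags target codes reached
    from more than one source.
    """
    target_framework = Framework(target_framework)
    if target_framework not in DOMAIN_FRAMEWORKS[source.domain]:
        raise CodemapError(
            f"target framework {target_framework.value} invalid for domain "
            f"{source.domain.value}"
        )
    if source_framework_column in lookup.columns:
        fws = set(lookup[source_framework_column].dropna().astype(str))
        if fws - {source.framework.value}:
            raise CodemapError(
                f"lookup table source framework(s) {sorted(fws)} do not match "
                f"codelist framework {source.framework.value}"
            )
    pairs = _normalise_pairs(lookup, "lookup") if len(lookup) else pd.DataFrame(
        columns=["source_code", "target_code"]
    )
    over = (
        _normalise_pairs(overrides, "overrides")
        if overrides is not None and len(overrides)
        else None
    )

    lookup_targets: dict[str, set[str]] = {}
    for src, grp in pairs.groupby("source_code"):
        lookup_targets[str(src)] = set(grp["target_code"])
    override_targets: dict[str, set[str]] = {}
    if over is not None:
        for src, grp in over.groupby("source_code"):
            override_targets[str(src)] = set(grp["target_code"])

    rows = []
    target_sources: dict[str, set[str]] = {}
    for code in sorted(source.codes):
        if code in override_targets:
            targets = override_targets[code]
            status = MappingStatus.MANUAL_OVERRIDE
        elif code in lookup_targets:
            targets = lookup_targets[code]
            status = MappingStatus.MAPPED
        else:
            targets = set()
            status = MappingStatus.UNMAPPED
        for t in targets:
            target_sources.setdefault(t, set()).add(code)
        rows.append(
            {
                "source_code": code,
                "status": status.value,
                "targets": ";".join(sorted(targets)),
                "n_targets": len(targets),
            }
        )
    audit_sources = pd.DataFrame(
        rows, columns=["source_code", "status", "targets", "n_targets"]
    )
    multi = {t: s for t, s in target_sources.items() if len(s) > 1}
    audit_sources["flagged"] = audit_sources["source_code"].map(
        lambda c: any(c in srcs for srcs in multi.values())
    ) if len(audit_sources) else pd.Series(dtype=bool)
    flagged_targets = pd.DataFrame(
        [
            {"target_code": t, "n_sources": len(s), "source_codes": ";".join(sorted(s))}
            for t, s in sorted(multi.items())
        ],
        columns=["target_code", "n_sources", "source_codes"],
    )
    target = Codelist(
        source.condition_id,
        target_framework,
        source.domain,
        frozenset(target_sources),
    )
    audit = MappingAudit(sources=audit_sources, flagged_targets=flagged_targets)
    logger.info(
        "mapped %s: %d source codes -> %d target codes (%d unmapped, %d flagged targets)",
        source.condition_id, len(source), len(target), audit.n_unmapped, len(flagged_targets),
    )
    return target, audit
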