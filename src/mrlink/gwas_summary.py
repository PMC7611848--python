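"""Reading, validation, instrument selection and harmonization of GWAS
summary statistics.

Two-sample Mendelian randomization starts from per-variant association
summaries for an exposure and for one or more outcomes.  This module turns
delimited summary-statistic tables into analysis-ready instrument sets:

1. :func:`read_summary_table` parses and validates per-variant records;
2. :func:`select_instruments` applies the genome-wide significance filter,
   a pleiotropy exclusion list, and greedy LD pruning;
3. :func:`substitute_proxies` swaps instruments missing from the outcome
   GWAS for high-LD proxy variants;
4. :func:`harmonize` aligns exposure and outcome effect sizes to the
   exposure-increasing allele, resolving strand flips and palindromic
   (A/T, C/G) ambiguity.

Every dropped variant is recorded in a provenance log with a
machine-readable reason code, so a pipeline run can report exactly how an
instrument set was arrived at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SummaryRecord",
    "InstrumentSet",
    "HarmonizedInstrument",
    "ProvenanceEvent",
    "ConfigurationError",
    "InputError",
    "InstrumentError",
    "read_summary_table",
    "read_ld_table",
    "read_proxy_table",
    "read_exclusion_list",
    "select_instruments",
    "substitute_proxies",
    "harmonize",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: unordered allele pairs that are their own strand complement
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

DEFAULT_COLUMNS = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
}


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input file."""


class InputError(ValueError):
    """An input table is empty or structurally invalid."""


class InstrumentError(ValueError):
    """A selection or harmonization step left zero usable instruments."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is in SD units for continuous traits and log-odds for binary
    traits; ``eaf`` is the effect-allele frequency (``None`` when the source
    GWAS does not report it).  ``proxy_of``/``proxy_sign`` are populated by
    :func:`substitute_proxies` when the record stands in for a missing
    instrument.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    proxy_of: str | None = None
    proxy_sign: int = 1

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: non-positive SE")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: p-value outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: EAF outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class ProvenanceEvent:
    """A kept/dropped decision for one variant at one selection stage."""

    variant_id: str
    action: str  # "kept" | "dropped" | "substituted"
    reason: str  # machine-readable code, e.g. "pvalue_above_threshold"
    detail: str = ""


@dataclass
class InstrumentSet:
    """An ordered set of exposure instruments plus its selection history."""

    exposure_name: str
    exposure_scale: str  # "per_sd" | "per_logodds"
    records: list[SummaryRecord]
    provenance_log: list[ProvenanceEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exposure_scale not in ("per_sd", "per_logodds"):
            raise ValueError(f"unknown exposure scale {self.exposure_scale!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant ids in instrument set")

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome effect pair expressed on a shared effect allele.

    After harmonization the effect allele is the exposure-increasing one,
    so ``beta_x >= 0`` always.  ``flipped`` records whether the outcome
    effect was negated to reach that orientation; ``proxy_of`` carries the
    original instrument id when a proxy variant supplied the outcome
    association.
    """

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    flipped: bool = False
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if self.beta_x < 0:
            raise ValueError(f"{self.variant_id}: beta_x must be >= 0 after harmonization")
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.variant_id}: SEs must be positive")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    scale: str = "per_sd",
    sep: str | None = None,
) -> tuple[list[SummaryRecord], list[ProvenanceEvent]]:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path
        TSV or CSV file with a header row.  The delimiter is sniffed when
        ``sep`` is None.
    column_map
        Mapping from the seven semantic names (``variant_id``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pvalue``) to the file's column headers.  Unmentioned names use
        the semantic name itself.  ``eaf`` may map to None for files
        without frequencies.
    scale
        Recorded by callers constructing an :class:`InstrumentSet`; not
        used for validation here.

    Returns
    -------
    (records, drop_log)
        Valid records in file order, and one :class:`ProvenanceEvent` per
        dropped row naming the 1-based data row and the failed check.

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is missing from the header.
    InputError
        if no row survives validation.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    for sem in mandatory:
        if colmap[sem] not in df.columns:
            raise ConfigurationError(
                f"column {colmap[sem]!r} (for {sem}) missing from {path}"
            )
    has_eaf = colmap.get("eaf") is not None and colmap["eaf"] in df.columns

    records: list[SummaryRecord] = []
    drop_log: list[ProvenanceEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        vid = str(row[colmap["variant_id"]])
        try:
            eaf = None
            if has_eaf and pd.notna(row[colmap["eaf"]]):
                eaf = float(row[colmap["eaf"]])
            se = float(row[colmap["se"]])
            if not se > 0:
                raise ValueError("non-positive SE")
            rec = SummaryRecord(
                variant_id=vid,
                effect_allele=str(row[colmap["effect_allele"]]).upper(),
                other_allele=str(row[colmap["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(row[colmap["beta"]]),
                se=se,
                pvalue=float(row[colmap["pvalue"]]),
            )
        except (ValueError, TypeError) as exc:
            drop_log.append(
                ProvenanceEvent(vid, "dropped", "validation_failed", f"row {i}: {exc}")
            )
            continue
        records.append(rec)

    if not records:
        raise InputError(f"no valid summary rows in {path}")
    return records, drop_log


def read_ld_table(path, sep: str | None = None) -> dict[frozenset, float]:
    """Read a three-column (id_a, id_b, r2) table; symmetric by construction."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] < 3:
        raise InputError(f"LD table {path} needs columns id_a, id_b, r2")
    table: dict[frozenset, float] = {}
    for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
        table[frozenset((str(a), str(b)))] = float(r2)
    return table


def read_proxy_table(path, sep: str | None = None) -> dict[str, list[tuple[str, float, int]]]:
    """Read a four-column (target_id, proxy_id, r2, sign) proxy table."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.shape[1] < 4:
        raise InputError(f"proxy table {path} needs columns target_id, proxy_id, r2, sign")
    out: dict[str, list[tuple[str, float, int]]] = {}
    for t, p, r2, sign in df.iloc[:, :4].itertuples(index=False):
        sign = int(sign)
        if sign not in (1, -1):
            raise InputError(f"proxy table sign must be +1 or -1, got {sign}")
        out.setdefault(str(t), []).append((str(p), float(r2), sign))
    return out


def read_exclusion_list(path) -> set[str]:
    """One variant id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        }


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

def select_instruments(
    records: Sequence[SummaryRecord],
    exposure_name: str = "exposure",
    exposure_scale: str = "per_sd",
    p_threshold: float = 5e-8,
    ld_table: Mapping[frozenset, float] | None = None,
    ld_max: float = 0.01,
    exclusion_list: Iterable[str] = (),
) -> InstrumentSet:
    """Select independent genome-wide-significant instruments.

    Records with ``pvalue < p_threshold`` are kept, exclusion-list members
    removed, then LD is pruned greedily: survivors are visited in ascending
    p-value order (ties broken by variant id) and a variant is dropped if
    its R² with any already-kept variant is ``>= ld_max``.  Variant pairs
    absent from ``ld_table`` are treated as uncorrelated — instrument lists
    from a GWAS are normally pre-clumped, so absence means "different
    region".

    Raises
    ------
    InstrumentError
        naming the first filter that emptied the set.
    """
    log: list[ProvenanceEvent] = []
    exclusion = set(exclusion_list)

    survivors = []
    for r in records:
        if not r.pvalue < p_threshold:
            log.append(ProvenanceEvent(r.variant_id, "dropped", "pvalue_above_threshold",
                                       f"p={r.pvalue:.3g} >= {p_threshold:.3g}"))
        else:
            survivors.append(r)
    if not survivors:
        raise InstrumentError(f"{exposure_name}: p-value filter removed all records")

    kept_after_excl = []
    for r in survivors:
        if r.variant_id in exclusion:
            log.append(ProvenanceEvent(r.variant_id, "dropped", "exclusion_list", ""))
        else:
            kept_after_excl.append(r)
    if not kept_after_excl:
        raise InstrumentError(f"{exposure_name}: exclusion list removed all records")

    ld = dict(ld_table) if ld_table else {}
    ordered = sorted(kept_after_excl, key=lambda r: (r.pvalue, r.variant_id))
    kept: list[SummaryRecord] = []
    for r in ordered:
        clash = next(
            (k.variant_id for k in kept
             if ld.get(frozenset((r.variant_id, k.variant_id)), 0.0) >= ld_max),
            None,
        )
        if clash is not None:
            log.append(ProvenanceEvent(r.variant_id, "dropped", "ld_prune",
                                       f"R2 >= {ld_max} with {clash}"))
        else:
            kept.append(r)
            log.append(ProvenanceEvent(r.variant_id, "kept", "selected", ""))
    if not kept:  # pragma: no cover - LD pruning always keeps the first variant
        raise InstrumentError(f"{exposure_name}: LD pruning removed all records")

    # restore input order for determinism independent of the prune order
    kept_ids = {r.variant_id for r in kept}
    final = [r for r in records if r.variant_id in kept_ids]
    return InstrumentSet(exposure_name, exposure_scale, final, log)


def substitute_proxies(
    instruments: InstrumentSet,
    outcome_ids: Iterable[str],
    proxy_table: Mapping[str, Sequence[tuple[str, float, int]]],
    r2_min: float = 0.9,
) -> InstrumentSet:
    """Replace instruments missing from the outcome GWAS with LD proxies.

    For each instrument absent from ``outcome_ids``, the highest-R² proxy
    with ``R² > r2_min`` that is present in the outcome is substituted; the
    proxy's allele-correspondence sign from the table is stored on the
    record so :func:`harmonize` can orient the outcome effect without
    comparing allele labels (a proxy's alleles generally differ from the
    target's).  Instruments with no admissible proxy are dropped and
    logged; drops are never fatal.
    """
    outcome_ids = set(outcome_ids)
    log = list(instruments.provenance_log)
    out: list[SummaryRecord] = []
    for rec in instruments.records:
        if rec.variant_id in outcome_ids:
            out.append(rec)
            continue
        candidates = [
            (pid, r2, sign)
            for pid, r2, sign in proxy_table.get(rec.variant_id, ())
            if r2 > r2_min and pid in outcome_ids
        ]
        if not candidates:
            log.append(ProvenanceEvent(rec.variant_id, "dropped", "no_proxy",
                                       f"absent from outcome, no proxy with R2 > {r2_min}"))
            continue
        pid, r2, sign = max(candidates, key=lambda c: c[1])
        out.append(replace(rec, variant_id=pid, proxy_of=rec.variant_id, proxy_sign=sign))
        log.append(ProvenanceEvent(rec.variant_id, "substituted", "proxy_used",
                                   f"proxy {pid} R2={r2:.3f} sign={sign:+d}"))
    return InstrumentSet(instruments.exposure_name, instruments.exposure_scale, out, log)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _eaf_side(eaf: float | None, tolerance: float) -> int | None:
    """-1 below 0.5, +1 above, None when missing or too close to call."""
    if eaf is None or abs(eaf - 0.5) < tolerance:
        return None
    return -1 if eaf < 0.5 else 1


def harmonize(
    instruments: InstrumentSet,
    outcome_records: Sequence[SummaryRecord],
    palindromic_policy: str = "infer_by_eaf",
    eaf_tolerance: float = 0.08,
) -> tuple[list[HarmonizedInstrument], list[ProvenanceEvent]]:
    """Align exposure and outcome effects to the exposure-increasing allele.

    For each instrument:

    1. if the exposure beta is negative, the effect/other alleles are
       swapped and the beta negated, so ``beta_x >= 0``;
    2. the outcome record (matched by instrument or proxy id) is oriented:
       same effect allele → keep, swapped alleles → negate ``beta_y``,
       strand-complemented alleles are recognised and treated the same;
    3. palindromic variants (A/T or C/G), whose alleles cannot resolve
       strand, follow ``palindromic_policy``: ``"drop"`` removes them;
       ``"infer_by_eaf"`` compares effect-allele frequencies — after label
       alignment, frequencies on the same side of 0.5 confirm the
       orientation and opposite sides toggle it; a frequency missing or
       within ``eaf_tolerance`` of 0.5 is ambiguous and the variant is
       dropped;
    4. irreconcilable allele sets are dropped and logged.

    Proxy records (``proxy_of`` set) skip allele comparison entirely: the
    proxy table's correspondence sign orients ``beta_y``.

    Raises
    ------
    InstrumentError
        if zero instruments harmonize.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    outcome_by_id = {r.variant_id: r for r in outcome_records}
    log: list[ProvenanceEvent] = []
    out: list[HarmonizedInstrument] = []

    for rec in instruments.records:
        oc = outcome_by_id.get(rec.variant_id)
        if oc is None:
            log.append(ProvenanceEvent(rec.variant_id, "dropped", "missing_in_outcome", ""))
            continue

        # step 1: orient exposure to its increasing allele
        if rec.beta < 0:
            ea, oa = rec.other_allele, rec.effect_allele
            beta_x = -rec.beta
            eaf_x = None if rec.eaf is None else 1.0 - rec.eaf
        else:
            ea, oa = rec.effect_allele, rec.other_allele
            beta_x = rec.beta
            eaf_x = rec.eaf

        if rec.proxy_of is not None:
            # orientation delegated to the proxy table's sign; exposure flip
            # in step 1 must carry through to the outcome as well
            sign = rec.proxy_sign * (-1 if rec.beta < 0 else 1)
            out.append(HarmonizedInstrument(
                rec.variant_id, beta_x, rec.se, sign * oc.beta, oc.se,
                flipped=sign < 0, proxy_of=rec.proxy_of,
            ))
            continue

        exp_pair = {ea, oa}
        oc_pair = {oc.effect_allele, oc.other_allele}
        oc_pair_comp = {COMPLEMENT[oc.effect_allele], COMPLEMENT[oc.other_allele]}

        palindromic = exp_pair in PALINDROMIC_PAIRS
        if not palindromic:
            if oc_pair == exp_pair:
                oc_ea = oc.effect_allele
            elif oc_pair_comp == exp_pair:
                oc_ea = COMPLEMENT[oc.effect_allele]
            else:
                log.append(ProvenanceEvent(rec.variant_id, "dropped",
                                           "allele_mismatch",
                                           f"exposure {ea}/{oa} vs outcome "
                                           f"{oc.effect_allele}/{oc.other_allele}"))
                continue
            flipped = oc_ea != ea
            beta_y = -oc.beta if flipped else oc.beta
            out.append(HarmonizedInstrument(rec.variant_id, beta_x, rec.se,
                                            beta_y, oc.se, flipped=flipped))
            continue

        # palindromic
        if oc_pair != exp_pair:
            log.append(ProvenanceEvent(rec.variant_id, "dropped", "allele_mismatch",
                                       "palindromic pair mismatch"))
            continue
        if palindromic_policy == "drop":
            log.append(ProvenanceEvent(rec.variant_id, "dropped", "palindromic", ""))
            continue

        # label alignment first, then frequency check toggles on disagreement
        flipped = oc.effect_allele != ea
        beta_y = -oc.beta if flipped else oc.beta
        eaf_y = oc.eaf
        if flipped and eaf_y is not None:
            eaf_y = 1.0 - eaf_y
        side_x = _eaf_side(eaf_x, eaf_tolerance)
        side_y = _eaf_side(eaf_y, eaf_tolerance)
        if side_x is None or side_y is None:
            log.append(ProvenanceEvent(rec.variant_id, "dropped", "palindromic_ambiguous",
                                       f"eaf_x={eaf_x} eaf_y={oc.eaf}"))
            continue
        if side_x != side_y:
            flipped = not flipped
            beta_y = -beta_y
        out.append(HarmonizedInstrument(rec.variant_id, beta_x, rec.se,
                                        beta_y, oc.se, flipped=flipped))

    if not out:
        raise InstrumentError(
            f"{instruments.exposure_name}: zero instruments harmonized")
    return out, log
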