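"""Cross-study harmonization, record linkage, and the pooled analysis sets.

The two registries are aligned to a shared covariate schema, trial patients
with a chart-review follow-up extension are linked by identifier (the trial
record is the primary source inside its own observation window), patients
without a completed post-index clinical assessment are excluded, and the
remainder is partitioned into the DVS analysis set and the SoC/placebo
analysis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import PatientRecord

logger = logging.getLogger(__name__)


@dataclass
class MappingSpec:
    """Per-variable alignment rules.

    ``variables`` maps a target variable name to a per-source rule:
    ``{source: {"from": source_var, "values": {src_value: target_value}}}``.
    A variable absent from one source's rules is treated as not collected
    there and dropped from the shared schema (with a warning). Value maps
    must be bijective per variable and source.
    """

    variables: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "MappingSpec":
        """Load the per-variable rules from a YAML or JSON file."""
        import json

        import yaml

        with open(path) as fh:
            raw = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
        return cls(variables=raw.get("variables", raw) or {})

    def validate(self, sources) -> None:
        for target, rules in self.variables.items():
            for src, rule in rules.items():
                vm = rule.get("values")
                if vm is not None and len(set(vm.values())) != len(vm):
                    raise ValueError(
                        f"mapping for {target!r} from source {src!r} is not bijective"
                    )


@dataclass
class PooledDataset:
    """One analysis set (DVS or SoC/placebo) with per-record provenance."""

    records: list
    analysis_set: str  # "DVS_SET" | "SOC_SET"
    retention: dict = field(default_factory=dict)  # per-source kept/excluded counts

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate patient_id within {self.analysis_set}")
        if any(not r.has_post_index_assessment for r in self.records):
            raise ValueError("pooled set contains records without a post-index assessment")


def align_variables(raw_tables: dict, mapping_spec: MappingSpec | None = None) -> list:
    """Bring per-source record lists onto one shared schema.

    ``raw_tables`` maps a source tag to a list of :class:`PatientRecord`.
    Variables collected in only a subset of sources are dropped from every
    record (the downstream covariate-adjusted models require covariates
    shared by all sources); category codings are relabelled through the
    per-source value maps.
    """
    if mapping_spec is None:
        mapping_spec = MappingSpec()
    mapping_spec.validate(raw_tables.keys())

    per_source_vars = {}
    for src, records in raw_tables.items():
        observed = set()
        for r in records:
            observed.update(r.covariates.keys())
        # apply renames declared in the mapping
        for target, rules in mapping_spec.variables.items():
            if src in rules:
                frm = rules[src].get("from", target)
                if frm in observed:
                    observed.discard(frm)
                    observed.add(target)
        per_source_vars[src] = observed

    shared = set.intersection(*per_source_vars.values()) if per_source_vars else set()
    dropped = set.union(*per_source_vars.values()) - shared if per_source_vars else set()
    if dropped:
        logger.warning("variables not shared by all sources dropped: %s", sorted(dropped))

    # type compatibility check across sources for each target variable
    for target, rules in mapping_spec.variables.items():
        kinds = set()
        for src, rule in rules.items():
            vm = rule.get("values")
            if vm:
                kinds.add(type(next(iter(vm.values()))))
        if len(kinds) > 1:
            raise ValueError(
                f"conflicting mapping for {target!r}: sources map to incompatible "
                f"types {sorted(k.__name__ for k in kinds)}"
            )

    out = []
    for src, records in raw_tables.items():
        for r in records:
            r = r.copy()
            cov = {}
            for target in shared:
                rule = mapping_spec.variables.get(target, {}).get(src, {})
                frm = rule.get("from", target)
                val = r.covariates.get(frm)
                vm = rule.get("values")
                if vm is not None and val is not None:
                    if val not in vm:
                        raise ValueError(
                            f"value {val!r} of {frm!r} in source {src!r} has no mapping"
                        )
                    val = vm[val]
                cov[target] = val
            r.covariates = cov
            r.source = r.source or src
            out.append(r)
    return out


def link_and_resolve(trial_records, followup_records, require_link: bool = True) -> list:
    """Merge trial records with their chart-review follow-up extensions.

    For a linked patient the trial record is the primary source: follow-up
    visits are appended only after the trial's last follow-up week, and a
    follow-up censoring event is honoured only if it falls after that week.
    Follow-up patients with no matching trial identifier raise (orphans),
    unless ``require_link=False``, in which case they are appended as-is.
    """
    by_id = {r.patient_id: r for r in trial_records}
    orphans = [f.patient_id for f in followup_records if f.patient_id not in by_id]
    if orphans and require_link:
        raise ValueError(f"follow-up records with no matching trial id: {sorted(orphans)}")

    merged = {pid: r.copy() for pid, r in by_id.items()}
    for f in followup_records:
        if f.patient_id not in merged:
            merged[f.patient_id] = f.copy()
            continue
        base = merged[f.patient_id]
        cutoff = base.visits[-1].week if base.visits else 0.0
        extra = [v for v in f.visits if v.week > cutoff]
        if f.censor_event is not None and f.censor_event[0] > cutoff:
            if base.censor_event is None or f.censor_event[0] < base.censor_event[0]:
                base.censor_event = f.censor_event
        if base.censor_event is not None:
            extra = [v for v in extra if v.week <= base.censor_event[0]]
        base.visits = base.visits + extra
    return list(merged.values())


def _has_completed_assessment(r: PatientRecord, index_week: float = 0.0) -> bool:
    return any(v.week > index_week and v.eo_all_closed is not None for v in r.visits)


def apply_exclusions(records) -> tuple[PooledDataset, PooledDataset]:
    """Exclude patients without a completed post-index assessment; split by arm.

    A "completed clinical assessment" is a visit after the index week with a
    non-missing closure assessment. Returns ``(dvs_set, soc_set)`` with
    per-source retention counts attached to each.
    """
    kept, excluded = [], []
    for r in records:
        if _has_completed_assessment(r):
            r = r.copy()
            r.has_post_index_assessment = True
            kept.append(r)
        else:
            excluded.append(r)
    if excluded:
        logger.info("excluded %d records without a completed post-index assessment", len(excluded))

    def _retention(subset):
        ret: dict = {}
        for r in subset:
            src = r.source or r.study
            ret[src] = ret.get(src, 0) + 1
        return ret

    dvs = [r for r in kept if r.arm == "DVS"]
    soc = [r for r in kept if r.arm == "SOC"]
    dvs_set = PooledDataset(records=dvs, analysis_set="DVS_SET", retention=_retention(dvs))
    soc_set = PooledDataset(records=soc, analysis_set="SOC_SET", retention=_retention(soc))
    for ds in (dvs_set, soc_set):
        ds.retention["excluded_total"] = len(excluded)
    return dvs_set, soc_set
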