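"""Rule-based methanogen substrate calling and a generic boolean rule engine.

A MAG is confirmed as a methanogen by the presence of Mcr and Hdr complex
genes.  Substrate *potential* is then called from the annotation catalog:
hydrogenotrophic (Wood-Ljungdahl pathway + Mtr complex + relevant
hydrogenases), acetoclastic (Methanosarcinia with ACS/CODH plus acetyl-CoA
synthetase or acetate kinase + phosphotransacetylase) or methylotrophic
(a substrate:corrinoid methyltransferase, mtxB).  *Active* pathway use at a
sample is called from expressed genes: hydrogenotrophic needs at least one
Wood-Ljungdahl gene and one hydrogenase expressed, methylotrophic an
expressed mtxB, acetoclastic the acetate genes (acs, or ack and pta).
Active Methanotrichales are obligate acetoclasts.  MAGs expressing no
methanogenesis genes at a timepoint, or too few to meet any rule, are
"ignored".

Rules are plain config (YAML) in a small boolean grammar over gene-set
predicates and taxonomy guards, so the same engine evaluates the carbon-cycle
role tables users supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "RuleSet",
    "MethanogenCall",
    "RuleError",
    "evaluate_rule",
    "call_potential",
    "call_active",
    "pathway_expression_summary",
    "evaluate_ruleset",
]

ANNOTATION_COLUMNS = ("ko_id", "cazy_best_hit", "camper_id")


class RuleError(ValueError):
    """Malformed rule expression or reference to a missing gene set."""


@dataclass
class RuleSet:
    """Named gene sets plus rule expressions in the boolean grammar."""

    gene_sets: dict[str, frozenset[str]]
    confirmation: Mapping | None = None
    potential: dict[str, Mapping] = field(default_factory=dict)
    active: dict[str, Mapping] = field(default_factory=dict)
    obligate_acetoclast_taxonomy: Mapping | None = None
    pathway_groups: dict[str, str] = field(default_factory=dict)
    roles: dict[str, Mapping] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: Mapping) -> "RuleSet":
        gene_sets = {
            name: frozenset(str(x) for x in ids)
            for name, ids in config.get("gene_sets", {}).items()
        }
        for name, ids in gene_sets.items():
            if not ids:
                raise RuleError(f"gene set {name!r} is empty")
        return cls(
            gene_sets=gene_sets,
            confirmation=config.get("confirmation"),
            potential=dict(config.get("potential", {})),
            active=dict(config.get("active", {})),
            obligate_acetoclast_taxonomy=config.get("obligate_acetoclast_taxonomy"),
            pathway_groups=dict(config.get("pathway_groups", {})),
            roles=dict(config.get("roles", {})),
        )

    @classmethod
    def default(cls) -> "RuleSet":
        with resources.files("mireomics.data").joinpath("methanogen_rules.yaml").open() as fh:
            return cls.from_config(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass
class MethanogenCall:
    mag_id: str
    is_methanogen: bool
    potential: frozenset[str] = frozenset()
    evidence: list[str] = field(default_factory=list)

    @property
    def multifunctional(self) -> bool:
        return len(self.potential) > 1


def evaluate_rule(
    node: Mapping,
    gene_ids: frozenset[str],
    taxonomy: Mapping[str, str],
    rules: RuleSet,
    rule_id: str = "<anonymous>",
    evidence: list[str] | None = None,
) -> bool:
    """Evaluate one grammar node against a MAG's gene ids and taxonomy."""
    if not isinstance(node, Mapping) or len(node) != 1:
        raise RuleError(f"rule {rule_id!r}: node must have exactly one key, got {node!r}")
    (op, arg), = node.items()
    if op == "all":
        return all(evaluate_rule(n, gene_ids, taxonomy, rules, rule_id, evidence) for n in arg)
    if op == "any":
        # no short-circuit so that evidence is collected from every branch
        return any([evaluate_rule(n, gene_ids, taxonomy, rules, rule_id, evidence) for n in arg])
    if op == "not":
        return not evaluate_rule(arg, gene_ids, taxonomy, rules, rule_id, None)
    if op == "genes":
        set_name = arg.get("set")
        if set_name not in rules.gene_sets:
            raise RuleError(f"rule {rule_id!r}: unknown gene set {set_name!r}")
        k = int(arg.get("min", 1))
        hits = gene_ids & rules.gene_sets[set_name]
        ok = len(hits) >= k
        if ok and evidence is not None:
            evidence.append(f">= {k} of {set_name}: {','.join(sorted(hits)[:5])}")
        return ok
    if op == "taxonomy":
        col, value = arg.get("column"), arg.get("equals")
        ok = str(taxonomy.get(col, "")) == str(value)
        if ok and evidence is not None:
            evidence.append(f"{col} == {value}")
        return ok
    raise RuleError(f"rule {rule_id!r}: unknown operator {op!r}")


def _annotation_ids(catalog: pd.DataFrame, mask=None) -> frozenset[str]:
    sub = catalog if mask is None else catalog[mask]
    ids: set[str] = set()
    for col in ANNOTATION_COLUMNS:
        if col in sub.columns:
            ids.update(sub[col].dropna().astype(str))
    ids.discard("")
    return frozenset(ids)


def _taxonomy_of(catalog: pd.DataFrame, mag_id: str) -> dict[str, str]:
    rows = catalog[catalog["mag_id"] == mag_id]
    tax = {}
    for col in rows.columns:
        if col.startswith("tax_"):
            vals = rows[col].dropna().unique()
            if len(vals):
                tax[col] = str(vals[0])
    return tax


def call_potential(catalog: pd.DataFrame, rules: RuleSet | None = None) -> dict[str, MethanogenCall]:
    """Substrate-use potential per MAG from encoded genes.

    MAGs lacking Mcr/Hdr get ``is_methanogen=False`` (not an exception).
    A confirmed methanogen may have an empty potential set.
    """
    rules = rules or RuleSet.default()
    calls: dict[str, MethanogenCall] = {}
    for mag_id in catalog["mag_id"].unique():
        gene_ids = _annotation_ids(catalog, catalog["mag_id"] == mag_id)
        taxonomy = _taxonomy_of(catalog, mag_id)
        evidence: list[str] = []
        confirmed = (
            evaluate_rule(rules.confirmation, gene_ids, taxonomy, rules,
                          "confirmation", evidence)
            if rules.confirmation is not None
            else True
        )
        if not confirmed:
            calls[mag_id] = MethanogenCall(mag_id, False)
            continue
        potential = set()
        for label, node in rules.potential.items():
            if evaluate_rule(node, gene_ids, taxonomy, rules, label, evidence):
                potential.add(label)
        calls[mag_id] = MethanogenCall(mag_id, True, frozenset(potential), evidence)
    return calls


def call_active(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    call: MethanogenCall,
    rules: RuleSet | None = None,
    sample: str | None = None,
) -> frozenset[str] | str:
    """Pathways a methanogen MAG is actively using in a sample.

    Returns the active subset, or the string ``"ignored"`` when no
    methanogenesis genes are expressed or the expressed genes meet no rule.
    Active Methanotrichales are forced to {acetoclastic}.
    """
    rules = rules or RuleSet.default()
    if not call.is_methanogen:
        return "ignored"
    genes = catalog.loc[catalog["mag_id"] == call.mag_id, "gene_id"]
    sub = expr.loc[expr.index.intersection(genes)]
    col = sub[sample] if sample is not None else sub.max(axis=1)
    expressed_genes = col[col > 0].index
    expressed_ids = _annotation_ids(
        catalog.set_index("gene_id").loc[expressed_genes].reset_index()
    )
    taxonomy = _taxonomy_of(catalog, call.mag_id)
    any_methanogenesis = (
        "methanogenesis_any" in rules.gene_sets
        and bool(expressed_ids & rules.gene_sets["methanogenesis_any"])
    )
    active = set()
    for label, node in rules.active.items():
        if evaluate_rule(node, expressed_ids, taxonomy, rules, label):
            active.add(label)
    if not active:
        return "ignored"
    guard = rules.obligate_acetoclast_taxonomy
    if guard is not None and str(taxonomy.get(guard["column"], "")) == str(guard["equals"]):
        return frozenset({"acetoclastic"})
    if not any_methanogenesis:
        return "ignored"
    return frozenset(active)


def pathway_expression_summary(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    rules: RuleSet | None = None,
    mag_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Summed expression per methanogenesis pathway group per sample."""
    rules = rules or RuleSet.default()
    cat = catalog if mag_ids is None else catalog[catalog["mag_id"].isin(mag_ids)]
    cat = cat.set_index("gene_id")
    rows = {}
    for group, set_name in rules.pathway_groups.items():
        if set_name not in rules.gene_sets:
            raise RuleError(f"pathway group {group!r}: unknown gene set {set_name!r}")
        ids = rules.gene_sets[set_name]
        member = pd.Series(False, index=cat.index)
        for col in ANNOTATION_COLUMNS:
            if col in cat.columns:
                member |= cat[col].astype("string").isin(ids).fillna(False)
        genes = expr.index.intersection(member.index[member])
        rows[group] = expr.loc[genes].sum(axis=0)
    return pd.DataFrame(rows).T.rename_axis(index="pathway", columns="sample_id")


def evaluate_ruleset(
    catalog: pd.DataFrame,
    expr: pd.DataFrame | None,
    rules: RuleSet,
    which: str = "roles",
) -> pd.DataFrame:
    """Generic evaluation: every MAG receives all satisfied labels.

    ``which`` selects the rule table in the config (``roles``, ``potential``
    or ``active``).  When ``expr`` is given, predicates are evaluated on
    expressed gene ids (union over samples); otherwise on encoded ids.
    """
    table = getattr(rules, which, None)
    if not table:
        raise RuleError(f"ruleset has no rules under {which!r}")
    records = []
    for mag_id in catalog["mag_id"].unique():
        mag_mask = catalog["mag_id"] == mag_id
        if expr is None:
            ids = _annotation_ids(catalog, mag_mask)
        else:
            genes = catalog.loc[mag_mask, "gene_id"]
            sub = expr.loc[expr.index.intersection(genes)]
            on = sub.index[(sub > 0).any(axis=1)]
            ids = _annotation_ids(catalog.set_index("gene_id").loc[on].reset_index())
        taxonomy = _taxonomy_of(catalog, mag_id)
        for label, node in table.items():
            satisfied = evaluate_rule(node, ids, taxonomy, rules, label)
            records.append({"mag_id": mag_id, "label": label, "satisfied": satisfied})
    return pd.DataFrame.from_records(records)
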