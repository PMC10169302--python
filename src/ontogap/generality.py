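"""The "more general than" relation on attribute-value pairs and groups.

A pair (r2, v2) is *strictly more general* than (r1, v1) when one of four
conditions holds:

1. r1 = r2 and v1 is-a v2;
2. r1 is-a r2 and v1 = v2;
3. r1 is-a r2 and v1 is-a v2;
4. v1's own logical definition contains a pair (r_b, v2) such that a property
   chain r_a ∘ r_b ⊑ r2 exists with r1 = r_a or r1 is-a r_a.

Condition 4 is what lets e.g. (Causative agent, "Edetate") generalize
(Causative agent, "Sodium calcium edetate") when "Sodium calcium edetate"
carries (Is modification of, "Edetate") and the chain
Causative agent ∘ Is modification of ⊑ Causative agent is asserted.

A group G2 is strictly more general than a group G1 ≠ G2 when every pair of
G2 is the same as or more general than some pair of G1.  Note a group with
*fewer*, more general pairs is more general: dropping a constraint loosens
the definition.
"""

from __future__ import annotations

from .ontology import AttributeGroup, AttributeValuePair, LogicalDefinition, Ontology


def pair_more_general(o: Ontology, general: AttributeValuePair, specific: AttributeValuePair) -> bool:
    """True iff ``general`` is *strictly* more general than ``specific``.

    Irreflexive: a pair is never more general than itself; use
    :func:`pair_ge` for "same as or more general".
    """
    r1, v1 = specific.attribute, specific.value
    r2, v2 = general.attribute, general.value
    if r1 == r2 and o.is_subtype(v1, v2):
        return True
    if r1 != r2 and o.is_subtype(r1, r2) and (v1 == v2 or o.is_subtype(v1, v2)):
        return True
    return _chain_more_general(o, general, specific)


def _chain_more_general(o: Ontology, general: AttributeValuePair, specific: AttributeValuePair) -> bool:
    # condition 4: consult the value concept's own groups (not its closure)
    if specific.value not in o.concepts:
        return False
    value_def = o.own_groups(specific.value)
    for chain in o.property_chains:
        if chain.implied != general.attribute:
            continue
        if not (specific.attribute == chain.first or o.is_subtype(specific.attribute, chain.first)):
            continue
        for grp in value_def:
            for p in grp:
                if p.attribute == chain.second and p.value == general.value:
                    return True
    return False


def pair_ge(o: Ontology, general: AttributeValuePair, specific: AttributeValuePair) -> bool:
    """"Same as or more general than" on pairs."""
    return general == specific or pair_more_general(o, general, specific)


def group_more_general(o: Ontology, g2: AttributeGroup, g1: AttributeGroup) -> bool:
    """True iff ``g2`` is strictly more general than ``g1`` (requires g1 ≠ g2)."""
    if not g1.pairs or not g2.pairs:
        raise ValueError("attribute groups must be non-empty")
    if g1 == g2:
        return False
    return all(any(pair_ge(o, p2, p1) for p1 in g1) for p2 in g2)


def group_ge(o: Ontology, g2: AttributeGroup, g1: AttributeGroup) -> bool:
    return g1 == g2 or group_more_general(o, g2, g1)


def normalize_group(o: Ontology, g: AttributeGroup) -> AttributeGroup:
    """Drop pairs implied by a more specific sibling pair in the same group.

    Within a conjunction, a pair strictly more general than another pair of
    the group adds no constraint.  Pairs in a (pathological) mutual-generality
    relation are both kept.
    """
    kept = [
        p
        for p in g
        if not any(
            q != p and pair_more_general(o, p, q) and not pair_more_general(o, q, p)
            for q in g
        )
    ]
    return AttributeGroup(frozenset(kept)) if kept else g


def reduce_definition(o: Ontology, d: LogicalDefinition) -> LogicalDefinition:
    """Remove every group that is strictly more general than another group.

    Groups are first normalized (intra-group redundant pairs dropped), which
    unifies definitions that only differ by implied pairs and rules out the
    mutual-generality case of a group versus itself-plus-an-implied-pair.
    The removal pass tests each group against the *full* normalized set, so
    the result is independent of processing order, and a group is only
    removed when it is not also more specific than its witness (guarding
    against generality cycles).  Idempotent.
    """
    groups = frozenset(normalize_group(o, g) for g in d.groups)
    survivors = {
        g
        for g in groups
        if not any(
            h != g and group_more_general(o, g, h) and not group_more_general(o, h, g)
            for h in groups
        )
    }
    if not survivors and groups:
        # pathological generality cycle: keep one canonical representative
        survivors = {min(groups, key=_group_key)}
    return LogicalDefinition(frozenset(survivors))


def _group_key(g: AttributeGroup) -> tuple:
    return (len(g.pairs), tuple(sorted((p.attribute, p.value) for p in g)))
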