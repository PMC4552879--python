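"""Independent test oracles: a naive rule-by-rule somatic filter and a
brute-force small-parsimony enumerator.  These deliberately share no code
with the implementation they check."""

from itertools import product


def naive_somatic_calls(table, cfg):
    """Straight transcription of the filtering rules, one if per rule."""
    normal_id = None
    for sid, role in table.sample_roles.items():
        if role == "normal":
            normal_id = sid
    calls = {}
    for sid in table.sample_ids:
        role = table.sample_roles[sid]
        if role == "normal":
            continue
        called = set()
        for v in table.variants:
            o = v.observations[sid]
            n = v.observations[normal_id]
            ok = True
            if v.annotation.in_dbsnp:
                rescued = v.annotation.in_cosmic and cfg.dbsnp_excludes_unless_cosmic
                if not rescued:
                    ok = False
            if o.depth < cfg.min_depth_case:
                ok = False
            if n.depth < cfg.min_depth_normal:
                ok = False
            if o.alt_count < cfg.min_alt_reads:
                ok = False
            vaf = o.alt_count / o.depth if o.depth else 0.0
            if role == "plasma":
                if vaf < cfg.min_vaf_plasma:
                    ok = False
            else:
                if vaf < cfg.min_vaf_tumor:
                    ok = False
            if role == "plasma":
                if n.alt_count > cfg.max_normal_alt_reads:
                    ok = False
                if cfg.require_both_strands_plasma:
                    if o.alt_fwd == 0 or o.alt_rev == 0:
                        ok = False
            if ok:
                called.add(v.key)
        calls[sid] = called
    return calls


def _internal_nodes(topo):
    nodes = []

    def collect(t):
        if isinstance(t, tuple):
            nodes.append(t)
            for child in t:
                collect(child)

    collect(topo)
    return nodes


def brute_force_parsimony(topo, leaf_states):
    """Minimum state changes for one binary character by enumerating every
    0/1 assignment to the internal nodes of the rooted topology.

    ``topo`` is a nested tuple of pairs with string leaves; ``leaf_states``
    maps leaf name to 0/1.
    """
    internals = _internal_nodes(topo)
    best = None
    for assignment in product((0, 1), repeat=len(internals)):
        states = {id(t): s for t, s in zip(internals, assignment)}

        def state_of(t):
            return leaf_states[t] if isinstance(t, str) else states[id(t)]

        cost = 0
        for t in internals:
            for child in t:
                cost += state_of(child) != state_of(t)
        if best is None or cost < best:
            best = cost
    return best


def brute_force_fitch_length(topo, matrix):
    """Sum of brute-force minima over all characters of a MutationMatrix."""
    total = 0
    for row in matrix.characters:
        leaf_states = {sid: int(s) for sid, s in zip(matrix.samples, row)}
        total += brute_force_parsimony(topo, leaf_states)
    return total


def random_rooted_topology(leaves, rng):
    """Random rooted binary topology as nested tuples (join random pairs)."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]
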