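"""Independent brute-force reference implementations used only by tests."""


def brute_dbscan_spans(positions, eps, min_pts):
    """O(n^2) DBSCAN on 1-D points; returns sorted (min, max) per cluster.

    Core point: >= min_pts points (itself included) within eps. Clusters
    are connected components of cores under the within-eps relation; border
    points attach to the nearest core, ties to the lower-coordinate core.
    """
    pos = sorted(positions)
    n = len(pos)
    nbrs = [
        [j for j in range(n) if abs(pos[j] - pos[i]) <= eps]
        for i in range(n)
    ]
    core = [len(nbrs[i]) >= min_pts for i in range(n)]
    comp = [None] * n
    cid = -1
    for i in range(n):
        if core[i] and comp[i] is None:
            cid += 1
            stack = [i]
            comp[i] = cid
            while stack:
                u = stack.pop()
                for v in nbrs[u]:
                    if core[v] and comp[v] is None:
                        comp[v] = cid
                        stack.append(v)
    members = {c: [] for c in range(cid + 1)}
    for i in range(n):
        if core[i]:
            members[comp[i]].append(pos[i])
    for i in range(n):
        if core[i]:
            continue
        cands = [
            (abs(pos[j] - pos[i]), pos[j], comp[j])
            for j in range(n)
            if core[j] and abs(pos[j] - pos[i]) <= eps
        ]
        if cands:
            _, _, c = min(cands)
            members[c].append(pos[i])
    return sorted((min(v), max(v)) for v in members.values() if v)
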