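"""Detect the recombinant in the 15-site worked model.

Two parental haplotypes (p1, p2) diverge from a common ancestor, recombine
between sites 6 and 7, and the surviving product r1 accumulates one further
substitution. Both detectors must recover r1, its parents, and a breakpoint
interval containing the true crossover.
"""

from hapnetrec import (
    build_median_network,
    detect_rectangle_recombinants,
    encode_binary,
    external_branch,
    fig1_fixture,
    pnarec_scan,
    singleton_profile,
)

matrix, truth = fig1_fixture()
binary = encode_binary(matrix)

net = build_median_network(binary)
print("external branches (site labels from each haplotype to the rectangle):")
for name in ("p1", "p2", "r1"):
    eb = external_branch(net, name)
    print(f"  {name}: {sorted(eb.sites)}  (length {eb.length})")

[net_call] = detect_rectangle_recombinants(net, binary)
[pn_call] = pnarec_scan(binary)
prof = singleton_profile(binary)

print(f"\nsingleton counts: {prof.counts}")
for call in (net_call, pn_call):
    print(
        f"{call.method:>8}: recombinant {call.recombinant}, "
        f"parents {call.parent_forward} (5') / {call.parent_backward} (3'), "
        f"crossover within sites {call.interval}"
    )
print(f"true crossover: between sites {truth.breakpoint[0]} and {truth.breakpoint[1]}")
# The interval (5, 8) brackets the true breakpoint 6/7: the closest flanking
# sites at which r1 still matches each parent.
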