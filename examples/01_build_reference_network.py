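"""Build a normal-tissue reference network from control expression.

Generates block-correlated control samples, runs the co-expression
pipeline (adjacency -> TOM -> communities -> preservation filter ->
top-weight edge retention) and prints what survived.
"""

import cohesionnet as cn

config = cn.SimulationConfig(seed=7)
controls = cn.generate_controls(config)
print(f"controls: {controls.n_genes} genes x {controls.n_samples} samples")

# power 6 is the conventional unsigned-network soft threshold; pass
# power="auto" to select it from the scale-free topology fit instead
result = cn.build_reference(controls, power=6)

print(f"soft power: {result.soft_power}")
print("preservation filter (kept communities have Zsummary > 10):")
print(
    result.preservation.table[["community", "size", "zsummary", "kept"]]
    .round(1)
    .to_string(index=False)
)
net = result.network
print(f"retained {net.n_edges()} intra-community edges "
      f"(top 10% by TOM weight per community)")
# every edge weight is a TOM similarity in (0, 1]; these weights later
# define both shortest-path lengths (1/w) and connectivity loss
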