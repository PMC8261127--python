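"""Score intramodule lncRNA-mRNA pairs by the shared-miRNA hypergeometric
test and compare the recovered edges with the planted ones."""

from common import example_config

from afcerna import aggregate_networks, build_module_cerna, generate_dataset, hypergeom_p

ds = generate_dataset(example_config())
bio = ds.biotypes.to_dict()
planted = {(l, m) for l, m, _ in ds.truth["planted_pairs"]}

nets = []
for mod in sorted({m for m in ds.truth["module_labels"].values() if m != 0}):
    genes = [g for g, v in ds.truth["module_labels"].items() if v == mod]
    net = build_module_cerna(genes, bio, ds.mirna_db, module=mod, alpha=0.05)
    nets.append(net)
    print(f"module {mod}: {len(net.edges)} significant ceRNA edges")

agg = aggregate_networks(nets, ds.seed_genes)
recovered = {(e.lncrna, e.mrna) for e in agg.edges}
tp = len(recovered & planted)
print(f"precision {tp / len(recovered):.2f}, recall {tp / len(planted):.2f} "
      f"({tp} of {len(planted)} planted pairs recovered)")
print("known disease genes inside the network:", len(agg.disease_genes))

edge = agg.edges[0]
print(f"example edge {edge.lncrna}-{edge.mrna}: t={edge.t} shared miRNAs of "
      f"n={edge.n}/M={edge.M} targets, N={edge.N}, p={edge.p:.2e}")
print("  (p = upper-tail hypergeometric:",
      f"{hypergeom_p(edge.N, edge.M, edge.n, edge.t):.2e})")
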