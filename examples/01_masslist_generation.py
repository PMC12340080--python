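"""Generate a SIL-aware mass list for PC species.

Builds the combinatorial set of PC molecular species from a small chain
pool, expands them into every feasible stable-isotope-label placement
(native, singly and doubly labeled, mixed labels), and prints the
theoretical [M+H]+ m/z values an identification engine would screen for.
"""

from omegamap import (
    apply_sil_labels,
    build_masslist,
    default_label_registry,
    enumerate_molecular_species,
    parse_chain,
)

pool = [parse_chain(t) for t in ("16:0", "18:1(n−9)", "20:4(n−6)", "22:5(n−3)")]
species = enumerate_molecular_species("PC", pool)
print(f"{len(species)} native PC species from a pool of {len(pool)} chains")

registry = default_label_registry()
labeled = apply_sil_labels(species, list(registry), max_labeled_chains=2)
print(f"{len(labeled)} species after SIL expansion (incl. mixed labels)")

masslist = build_masslist(labeled, ["[M+H]+"])
print(masslist[["species_key", "adduct", "mz", "label_codes"]].head(12).to_string(index=False))
# Each labeled row's m/z exceeds its native counterpart by the exact summed
# heavy-atom shift, e.g. +17.1067 Da for the D17 (n-9) label.
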