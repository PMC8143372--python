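"""Call focal amplifications and classify resistance-related SCNAs.

A focal amplification must be <20 Mb, above +0.2 log2, gene-bearing, stand
0.2 (driver) / 0.58 (non-driver) above its 20 Mb flanks, and survive the
segmental-duplication and copy-number-polymorphism vetoes.
"""

import plasmacna as pc
from plasmacna import profiling
from plasmacna.focal import call_focal_amplifications, call_focal_deletions
from plasmacna.patients import classify_rrscna

genome = pc.make_genome(n_chrom=2, chrom_length=60_000_000, seed=1)
panel = pc.simulate_control_panel(genome, 10, pc.SimulationConfig(seed=3))
annotation = pc.AnnotationBundle.from_genome(genome)

# amplify a window around EGFR (a known driver) at 20% tumor fraction
egfr = genome.genes[genome.genes.name == "EGFR"].iloc[0]
event = pc.SimulatedEvent(egfr.chrom, int(egfr.start) - 500_000,
                          int(egfr.end) + 1_500_000, total_copies=4)
counts = pc.simulate_counts(genome, [event],
                            pc.SimulationConfig(tumor_fraction=0.2, seed=5))

profile = pc.normalize_against_panel(counts, panel, genome)
segments = pc.segment_profile(profile)
events = call_focal_amplifications(segments, annotation)
events += call_focal_deletions(segments, annotation)

for ev in events:
    print(f"{ev.direction} {ev.segment.chrom}:{ev.segment.start}-{ev.segment.end} "
          f"log2={ev.segment.mean_log2:+.3f} delta={ev.neighbor_delta:+.3f} "
          f"genes={','.join(ev.genes)}")
print("resistance-related genes:", classify_rrscna(events))
# EGFR amplification is an osimertinib-resistance SCNA (rrSCNA): it passes the
# driver neighbor-delta rule (0.2) because EGFR is on the driver list.
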