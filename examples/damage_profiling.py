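"""Deamination damage profiling and end-trim recommendation.

Simulates ancient-DNA reads with exponentially decaying terminal damage
(30% C->T at the 5' terminus, halving per position) plus a small uniform
error floor, writes/parses them as text SAM, applies the standard length
and mapping-quality filters, and recommends how many bases to mask.
"""

import tempfile
from pathlib import Path

from adnakit.damage import apply_read_filters, compute_damage, recommend_trim, trim_ends
from adnakit.samio import parse_sam
from adnakit.simulate import DamageModel, simulate_damaged_reads

model = DamageModel(d0=0.30, lam=0.5)
sam_path = Path(tempfile.mkdtemp()) / "simulated_reads.sam"
simulate_damaged_reads(50_000, model, error_rate=0.001, seed=11, out=sam_path)

reads = parse_sam(sam_path)
kept, counts = apply_read_filters(reads, min_length=30, min_mapq=30)
print(
    f"{counts.n_input} reads parsed; {counts.n_short} short and "
    f"{counts.n_low_mapq} low-MAPQ removed; {counts.n_retained} kept"
)

profile = compute_damage(kept)
print("\n5' C->T frequency by position (expected 0.30 * 0.5^(i-1)):")
for i in range(1, 7):
    print(f"  position {i}: {profile.ct5[i - 1]:.4f}")
print(f"interior mismatch baseline: {profile.interior_baseline:.5f}")

t = recommend_trim(profile)
print(f"\nrecommended symmetric trim: {t} bases per end")
trimmed = trim_ends(kept, t)
after = compute_damage(trimmed)
print(
    f"after masking, 5' position {t + 1} frequency: "
    f"{after.ct5[t]:.5f} (indistinguishable from baseline)"
)
print(
    "\nThe decaying C->T/G->A curves authenticate the reads as ancient;"
    "\nmasking the damaged termini keeps deamination out of genotypes."
)
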