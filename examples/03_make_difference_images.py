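"""Survival-ordered pairs, dimension raising and PNG output.

Generates every patient pair of a small TPM cohort (longer survivor first),
encodes each pair as a TLS image and its TSL complement, and writes the
PNGs plus a manifest. With G genes the image side is ceil(sqrt(G)) and the
trailing side^2 - G cells are zero-padded; for the full 60,483-gene
transcriptome that is a 246 x 246 image with 33 padded cells.
"""

import tempfile
from pathlib import Path

import survimage as sv

sim, _ = sv.simulate_cohort(sv.SimConfig(n_patients=5, n_genes=36, seed=1))
cohort, _ = sv.filter_cohort(sim)
cohort = sv.Cohort(records=cohort.records,
                   expression=sv.fpkm_to_tpm(cohort.expression))

pairs = sv.generate_pairs(cohort)
print(f"{cohort.n} patients -> {len(pairs)} pairs "
      f"-> {2 * len(pairs)} images (TLS + TSL)")
print("first pairs (longer survivor first):", pairs[:3])

images = sv.build_image_set(cohort)
tls = images[0]
print(f"image side {tls.side} for {tls.n_genes} genes, "
      f"{tls.pad_count} zero-padded cells")
print("TLS pixels row 0:", tls.pixels[0].tolist())
print("TSL pixels row 0:", images[1].pixels[0].tolist(),
      "(= 255 - TLS at data cells)")
print("full transcriptome side:", sv.matrix_side(60_483))

out = Path(tempfile.mkdtemp()) / "images"
manifest = sv.write_image_set(images, out)
print("wrote", len(images), "PNGs and", manifest.name, "to", out)
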