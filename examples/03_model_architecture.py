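"""The four-block complex network: shape trace, parameters, operations.

Builds the default 62-channel model and two structural ablations and
prints the per-block shape trace plus complexity accounting.
"""

from cveegnet.model import (
    FLOP_CONVENTION, ModelConfig, ModelVariant,
    build_model, build_variant, count_flops, count_parameters, trace_shapes,
)

cfg = ModelConfig()  # C=62 channels, T=200 bins, F1=8, D=2, F2=16, K=3
print("shape trace of the default model:")
for name, shape in trace_shapes(cfg):
    print(f"  {name:22s} {shape}")

model = build_model(cfg, seed=0)
print(f"\ntrainable complex parameters: {count_parameters(model):,} "
      f"({count_parameters(model) / 1e3:.2f} K)")
print(f"real operations per sample:   {count_flops(model) / 1e6:.2f} M")
print(f"  convention: {FLOP_CONVENTION}")

for name in ("no_spatial", "no_separable", "spatial_meanpool"):
    variant = build_variant(cfg, ModelVariant.from_name(name), seed=0)
    n = count_parameters(variant)
    print(f"variant {name:18s}: {n:,} complex parameters "
          f"(classifier input {variant.flatten_dim})")
# deleting the spatial block leaves the 62-channel axis uncompressed, which
# is why its classifier balloons to millions of parameters
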