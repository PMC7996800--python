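"""Print the exact layer-shape chains of every network in the package.

Shape inference is pure arithmetic over the convolution output-size formula
L' = floor((L - F + 2P)/S) + 1 (or ceil(L/S) for same padding, L*S for
same-padded transposed convolution) — no weights are allocated.  The landmark
widths: generator dense layer 12,544 and discriminator flatten 6,272 for
28x28 images; AlexNet conv1 55 and first FC input 9,216; VGG16 first FC
input 25,088.
"""

from cystaug import GeneratorPlan, DiscriminatorPlan, alexnet_plan, infer_shapes, vgg16_plan

gen = GeneratorPlan(28, 28)
disc = DiscriminatorPlan(28, 28)
print("DCGAN generator (28x28): ", " -> ".join(map(str, gen.shape_chain())))
print("DCGAN discriminator:     ", " -> ".join(map(str, disc.shape_chain())))
print(f"  dense width {gen.dense_units}, flatten width {disc.flatten_width}\n")

print("AlexNet (227x227x1):")
print("  " + " -> ".join(map(str, infer_shapes(alexnet_plan(), 227))))
print("VGG16 (224x224x1):")
print("  " + " -> ".join(map(str, infer_shapes(vgg16_plan(), 224))))
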