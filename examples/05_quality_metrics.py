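"""Full-reference quality indices on progressively degraded images."""

from abmff import add_salt_pepper, evaluate_pair, generate, two_region_spec

clean, _, _ = generate(two_region_spec(seed=2))

print("impulses |    psnr |   ssim |   fsim |   rmse")
for count in (0, 500, 2000, 5000):
    noisy = add_salt_pepper(clean, count=count, seed=3)
    r = evaluate_pair(clean, noisy)
    print(f"{count:8d} | {r.psnr:7.2f} | {r.ssim:6.4f} | {r.fsim:6.4f} | {r.rmse:6.2f}")

# PSNR is infinite for identical images and falls as impulses accumulate;
# SSIM (global statistics form) and FSIM (phase-congruency weighted) both
# degrade from their perfect score of 1.
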