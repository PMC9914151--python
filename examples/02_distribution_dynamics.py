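"""Track the shape of the efficiency distribution over time with KDE.

Loads the packaged 20-province efficiency panel and smooths each
observation year's cross-section with a Gaussian kernel (bandwidth
h = 0.9 * min(sd, IQR/1.34) * n^-0.2). The number of peaks measures
polarization (separate high/low clusters); the falling main-peak height
signals growing dispersion.
"""

import effimarkov as em

panel = em.datasets.load_efficiency_panel()
print("year  bandwidth  peaks  main peak (position, height)")
for year in (2011, 2013, 2015, 2017, 2019):
    values = panel.values_in(year)
    curve = em.gaussian_kde_curve(values, em.bandwidth_rule(values))
    shape = em.curve_shape(curve)
    print(f"{year}   {curve.bandwidth:7.4f}    {shape.n_peaks}     "
          f"({shape.main_peak[0]:.3f}, {shape.main_peak[1]:.3f})")
print("\nTwo peaks in every year: provinces cluster into a low- and a")
print("high-efficiency group; the declining main peak shows the high group")
print("spreading out over the decade.")
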