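d[E]/dt = -k0*[E]*[S] + k1*[ES] + 2*k2*[ES]
d[S]/dt = -k0*[E]*[S] + k1*[ES]
d[ES]/dt = k0*[E]*[S] - k1*[ES] - k2*[ES]
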