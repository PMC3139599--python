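d[E]/dt = -k0*[E]*[S] + k1*[SE] + k5*[EA]
d[S]/dt = -k0*[E]*[S] + k1*[SE] - k6*[S]*[ES] + k7*[SES] - k8*[S]*[EA] + k9*[SEA] - k14*[S]*[EAS] + k15*[SEAS]
d[SE]/dt = k0*[E]*[S] - k1*[SE] - k2*[SE] + k3*[ES] + k11*[SEA]
d[ES]/dt = k2*[SE] - k3*[ES] - k4*[ES] - k6*[S]*[ES] + k7*[SES]
d[EA]/dt = k4*[ES] - k5*[EA] - k8*[S]*[EA] + k9*[SEA]
d[P]/dt = k4*[ES] + k10*[SES]
d[SES]/dt = k6*[S]*[ES] - k7*[SES] - k10*[SES]
d[SEA]/dt = k8*[S]*[EA] - k9*[SEA] + k10*[SES] - k11*[SEA] - k12*[SEA] + k13*[EAS]
d[EAS]/dt = k12*[SEA] - k13*[EAS] - k14*[S]*[EAS] + k15*[SEAS]
d[SEAS]/dt = k14*[S]*[EAS] - k15*[SEAS]
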