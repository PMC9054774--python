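name,v_min_ms,v_max_ms,v_min_sink_ms,v_theta_min_ms,ld_max
Pigeon (Columba livia),8,22,,,6
Laggar falcon (Falco jugger),6.6,15.9,,12.5,10
Black vulture (Coragyps atratus),9.9,16.8,11.6,13.9,11.6
Harris' hawk (Parabuteo unicinctus),6.1,16.2,8.8,,10.9
Jackdaw (Corvus monedula),6,11,7.4,8.3,12.6
Common swift (Apus apus),7,11,8.1,9.4,12.5
Astro-mite,6,9.5,,,10
Dream-flight Alula,4.7,13,5,6.5,12
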