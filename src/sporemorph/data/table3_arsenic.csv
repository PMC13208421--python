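species,origin,fungarium_id,as_mg_kg
Cyanoboletus mediterraneensis,Greece,ACAM 2022-134,1.33
Cyanoboletus mediterraneensis,Israel,K-M001443116,3.39
Cyanoboletus mediterraneensis,Israel,K-M001443117,4.67
Cyanoboletus mediterraneensis,Italy,ACR-Hal-BP-25,2.74
Cyanoboletus mediterraneensis,Italy,K-M001445821,0.30
Cyanoboletus mediterraneensis,Italy,GS10270,1.43
Cyanoboletus mediterraneensis,Spain,VAL_Myco 1758,1.68
Cyanoboletus mediterraneensis,Spain,VAL_Myco 1757,0.72
Cyanoboletus poikilochromus,Israel,K-M001441521,0.34
Cyanoboletus poikilochromus,Israel,K-M001441523,7.14
Cyanoboletus poikilochromus,Israel,K-M001441529,0.55
Cyanoboletus poikilochromus,Spain,VAL_Myco 1755,0.36
Cyanoboletus poikilochromus,Spain,VAL_Myco 1756,0.55
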