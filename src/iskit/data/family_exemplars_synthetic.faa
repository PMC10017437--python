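>IS1|synthetic_exemplar 230 aa DDE-type transposase stand-in
MPQHCVHAFCYHVMETEDQFCVKNNKEGNTSTRQFFPLCIRHILMIFPYCVTAQIDFHTD
FWSFRSIPMAPGQSSYICWRRAFLDEMFEDWRPNYCFLFPWYWLTFAQYICAEQRLGSAA
HQKTEFSIRMIWTFADNTEKTCPCSVAHYQDTDECTWMMRWARLIVPWSDSFADNMDLIA
PKKPWMYNCLTNAEAGTVHAVAILVHLMHEAFRPLDNNTGYTAEHQDDYF
>IS4|synthetic_exemplar 320 aa DDE-type transposase stand-in
MVTDLNMYLGLWCHHKNQTSWTPPLYWAAPGQQTRGEYRAWIYDHHFWEVWQSVTQQKPK
KISCLSVVLPGEMAARHHEDCMDWVHTVIQCEEHTCKYHPGSSRFQMYMMRWDIFHMMTP
ASYQCRQEYNDRSKVYLDYNLVSRILEPVKQCKICCFQLARAAYDGYYDTMSGDFWGLTK
MGNKAEKEVADLMDKGHVKLAQGQWLHRMYTAPFYEGGVAKVPIQRPSTLFYCWKESSTG
CTDMKTKDITMVIIPFTAPCWYQAVFIEAWMRKRFHPTNRFNFLWGRVLCSVADTEIDSP
EGSYQVHTGYEYRSIMIMVW
>IS5|synthetic_exemplar 265 aa DDE-type transposase stand-in
MARFTEMRFLTGFRTFVKPLPIAHMFERIPSQCTFVTCVWPYSLKWTFKVVDDGFAKFAT
QTMARTYVWPEYNVRRCLMYYEGDTNANDFTNKLMTLAQVHKDCAADQMKTEGVNGGENK
GQYVDVNQVVLAYQHFRGPMEGWNEEFANVYKHNFSDACMPDGSHGDPGKAEHIYIHIKY
FWNWEIMNAQLYCLQIVTCIELNRKCSEVERNLVSEWALSEDVCRWWNIACCPMDPLGEM
SDWAKNEFYNHGQNETTVPFFSMPW
>IS66|synthetic_exemplar 472 aa DDE-type transposase stand-in
MGSFCDRNVVWIPPERKFMSGNLSEMPHCFGMGAIHVVCNDKSMVSRRFQSNCDNDTSCT
EMYWNNFMGTLTNAQIEVIVCPKTTVWKDYFHRDECGHHCKVSKWLKWDLHYRQETQWRA
FCEMKKRIPHENVHEIRCPIIFVYCNQLNCGDGKGMTYWRYSPLKHPWSKPLMEALFLVA
CMMWAAWCGHPNTFLHGEWDSYFRAENSWKDSKFINMSIICPMIAGFGPTWGGMPCFHWK
FNLIQKLKVRLGKEERNRNAMGHWSIYFEVCIARTPELQWQTQAYGWAAFHIPYQQFYHW
MRCHDGANVLGGQGIDRWPMRSEIDRYDRQGFFFLWLNEPMNDLTMYQAKVGQWCTRSEN
AIFEIPMWVWHLQNVPVAMQQWDIHYDSVEFCQEGNDAHNDPLEVRWRQCYFVCWNDGGW
GMPGKCPRREFTIFYLDVAFKLTCPDTPACSRWMIFETLPHAPSKDFIYRGL
>IS630|synthetic_exemplar 187 aa DDE-type transposase stand-in
MPYRKCMKHEKCWLFWLESIDASPAISPNWHRVAEMDNKETFTCEANWYHGVSPHWRSNI
DYHPQVYSRYQNAIISDYNSKHYPLNSTYRWNTEANCPHIWNRNQCYMWDLYADNQTRNA
PNKYQRAHFMDKQKPFNPPEQCCIGKARSRFRMKCSRFYWDTGAKSCWDNRTEYQEEPCK
DGDPWCE
>IS701|synthetic_exemplar 432 aa DDE-type transposase stand-in
MNQSFLLLRPCHRYKWPWMKKKRHLWDVQCPHTVMAACPWNASLQCHLPACLVSVWSTVS
KTNIDIAKHVGWCRAGVWIPKFHPRPDTCYRLFPTQSKTQMEFDLRWATYEDAYYYGQHD
RKDNMRMLSLYKSDEAWSGGGRWCELMYMEMSREYFIVNQKKIDCVRGNWLATSHCMQYA
NTCPYESPQPGVVPVQLAHPIHTRWNIIDQIAICFDIFREFRDFSRWSKKHLMNLHSRWA
HCMRPMHGPYIQNLVKFNAQHAPIAVPKTHPSYMEFTDITIIVLCWCQKTPQRYDYHIGP
CICAEPWHFWFIIDCLQCSAFCLSCLPNYCTLWDEGYNPDQDSSWSLLLLVSGNTAGRKG
YIREQWVEYTREVDNDKAISLHSKIFIRYQACVTKQRRGCVWQGSGNMIQPPQISSLGCI
IVESHMWWIYPA
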